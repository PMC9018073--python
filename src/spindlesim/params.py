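"""Model parameters for the anaphase B spindle simulation.

All lengths are in micrometres (µm), all times in minutes, all speeds in
µm/min. The defaults are the wild-type values measured in fission yeast:
microtubules grow at 1.6 µm/min in early anaphase, shrink at 3.6 µm/min,
and each spindle pole slides outward at 0.35 µm/min. A fixed budget of
rescue factor (``R``, in µm/min — an integrated rate over the midzone
overlap) is distributed along the antiparallel overlap, shaped along the
midzone by a Beta(alpha, beta) density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

__all__ = ["SimParams", "wild_type_params", "ase1_delta_params"]

_VARIANTS = ("midzone", "uniform")


@dataclass(frozen=True)
class SimParams:
    """The complete parameter set of the spindle model.

    Attributes
    ----------
    v_p : float
        Microtubule growth (polymerisation) speed, µm/min.
    v_d : float
        Microtubule shrinkage (depolymerisation) speed, µm/min.
    v_s : float
        Sliding speed of each pole away from the spindle centre, µm/min
        (so the spindle elongates at ``2 * v_s``).
    R : float
        Integrated rescue rate, µm/min: the fixed total amount of rescue
        activity distributed over the midzone overlap (or over the whole
        microtubule length in the ``uniform`` variant).
    n_cat : float
        Number of independent sub-steps required for catastrophe; the
        growth-duration CDF is ``(1 - exp(-theta*t))**n``. May be
        non-integer.
    theta_cat : float
        Rate of each catastrophe sub-step, 1/min.
    mu_mz, sigma_mz : float
        Mean and SD (µm) of the normal fit of midzone length; each run
        draws one midzone length from this distribution (truncated to
        positive values).
    alpha, beta : float
        Shape parameters of the Beta density concentrating rescue
        activity along the midzone (alpha=beta=1 is uniform; larger
        alpha skews activity toward the midzone edge distal to the
        growing microtubule's own pole).
    h : float
        Integration timestep, min.
    variant : str
        ``"midzone"`` (rescue confined to the midzone overlap) or
        ``"uniform"`` (rescue anywhere on the spindle, emulating loss of
        the midzone crosslinker).
    t_max : float
        Simulated duration cap, min.
    n_mts0 : int
        Initial microtubule count (9: five from one pole, four from the
        other, on a 3x3 chequerboard).
    L_mt0 : float
        Initial microtubule length, µm.
    S0 : float
        Initial spindle (pole-to-pole) length, µm.
    """

    v_p: float = 1.6
    v_d: float = 3.6
    v_s: float = 0.35
    R: float = 55.0
    n_cat: float = 8.53
    theta_cat: float = 3.17
    mu_mz: float = 1.23
    sigma_mz: float = 0.25
    alpha: float = 4.0
    beta: float = 2.0
    h: float = 0.01
    variant: str = "midzone"
    t_max: float = 20.0
    n_mts0: int = 9
    L_mt0: float = 3.0
    S0: float = 4.0
    # normalisation 1/B(alpha, beta); derived, not user-set
    _beta_norm: float = field(init=False, repr=False, compare=False, default=0.0)

    def __post_init__(self) -> None:
        for name in ("v_p", "v_d", "v_s", "h", "mu_mz", "sigma_mz",
                     "theta_cat", "n_cat", "alpha", "beta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.R < 0:
            raise ValueError(f"R must be >= 0, got {self.R}")
        if self.variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS}, got {self.variant!r}")
        if self.L_mt0 > self.S0:
            raise ValueError("initial microtubule length cannot exceed spindle length")
        norm = math.exp(math.lgamma(self.alpha + self.beta)
                        - math.lgamma(self.alpha) - math.lgamma(self.beta))
        object.__setattr__(self, "_beta_norm", norm)

    def beta_pdf(self, x: float) -> float:
        """Beta(alpha, beta) density on [0, 1], endpoints taken as limits."""
        a, b = self.alpha, self.beta
        if x < 0.0 or x > 1.0:
            return 0.0
        if x == 0.0:
            return self._beta_norm if a == 1.0 else (math.inf if a < 1.0 else 0.0)
        if x == 1.0:
            return self._beta_norm if b == 1.0 else (math.inf if b < 1.0 else 0.0)
        return self._beta_norm * x ** (a - 1.0) * (1.0 - x) ** (b - 1.0)

    def with_(self, **overrides) -> "SimParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **overrides)

    @staticmethod
    def field_names() -> tuple[str, ...]:
        return tuple(f.name for f in fields(SimParams) if f.init)


def wild_type_params(**overrides) -> SimParams:
    """Wild-type parameter set (midzone-localised rescue, R = 55 µm/min)."""
    return SimParams(**overrides)


def ase1_delta_params(**overrides) -> SimParams:
    """Parameter preset emulating deletion of the midzone crosslinker.

    Rescue activity is spread uniformly along all microtubules
    (``variant="uniform"``), the rescue budget drops to R = 34 µm/min and
    the catastrophe-time parameters switch to n = 6.8, theta = 2.5 1/min.
    """
    base = dict(variant="uniform", R=34.0, n_cat=6.8, theta_cat=2.5)
    base.update(overrides)
    return SimParams(**base)
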