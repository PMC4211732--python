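"""Half-normal detection function, link scales and detection covariates.

Detection of an animal with activity center ``s`` at a detector ``x`` is
Bernoulli per occasion with

    p = g0 * exp(-d(s, x)^2 / (2 sigma^2)),

where ``g0`` is the detection probability at zero distance and ``sigma``
(km) the spatial scale of the decline.  ``g0`` is modelled on the logit
scale and may depend on an occasion factor (t), a behavioural response to
prior detection (one of b / bk / Bk) or sex; ``sigma`` is log-linear and
may depend on sex.  Behavioural responses act on ``g0`` only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import expit, logit

__all__ = [
    "ModelSpec",
    "BehaviorCovariate",
    "halfnormal_p",
    "build_behavior_covariates",
    "detection_probabilities",
    "DetectionProbabilities",
]

BEHAVIOR_TYPES = ("b", "bk", "Bk")
_G0_TERMS = ("intercept", "t", "b", "bk", "Bk", "sex")
_SIGMA_TERMS = ("intercept", "sex")


@dataclass(frozen=True)
class ModelSpec:
    """A detection-model formula: which terms act on g0 and sigma.

    Links are fixed: logit for g0, log for sigma, log for density D and
    logit for the sex-mixture proportion psi (present whenever a sex term
    appears anywhere in the model).
    """

    g0_terms: tuple = ("intercept",)
    sigma_terms: tuple = ("intercept",)
    detectfn: str = "halfnormal"

    def __post_init__(self) -> None:
        if self.detectfn != "halfnormal":
            raise ValueError("only the half-normal detection function is supported")
        object.__setattr__(self, "g0_terms", tuple(self.g0_terms))
        object.__setattr__(self, "sigma_terms", tuple(self.sigma_terms))
        for t in self.g0_terms:
            if t not in _G0_TERMS:
                raise ValueError(f"unknown g0 term {t!r}")
        for t in self.sigma_terms:
            if t not in _SIGMA_TERMS:
                raise ValueError(f"unknown sigma term {t!r}")
        if "intercept" not in self.g0_terms or "intercept" not in self.sigma_terms:
            raise ValueError("both parameters need an intercept term")
        n_beh = sum(t in BEHAVIOR_TYPES for t in self.g0_terms)
        if n_beh > 1:
            raise ValueError("at most one behavioural term (b, bk or Bk) is allowed")

    # -- structure queries ---------------------------------------------------
    @property
    def behavior(self) -> Optional[str]:
        for t in self.g0_terms:
            if t in BEHAVIOR_TYPES:
                return t
        return None

    @property
    def uses_t(self) -> bool:
        return "t" in self.g0_terms

    @property
    def uses_sex(self) -> bool:
        return "sex" in self.g0_terms or "sex" in self.sigma_terms

    @property
    def name(self) -> str:
        def label(terms):
            extras = [t for t in terms if t != "intercept"]
            return ", ".join(extras) if extras else "."
        return f"g0({label(self.g0_terms)}), sigma({label(self.sigma_terms)})"

    @classmethod
    def from_formula(cls, formula: str) -> "ModelSpec":
        """Parse e.g. ``"g0~bk, sigma~sex"`` (``1`` or ``.`` = intercept only)."""
        g0_terms: list = ["intercept"]
        sigma_terms: list = ["intercept"]
        for part in formula.split(","):
            part = part.strip()
            if not part:
                continue
            if "~" not in part:
                raise ValueError(f"cannot parse model term {part!r}")
            lhs, rhs = (s.strip() for s in part.split("~", 1))
            terms = [t.strip() for t in rhs.split("+") if t.strip() not in ("1", ".", "")]
            if lhs == "g0":
                g0_terms += terms
            elif lhs in ("sigma", "s"):
                sigma_terms += terms
            else:
                raise ValueError(f"unknown parameter {lhs!r} in formula")
        return cls(tuple(g0_terms), tuple(sigma_terms))

    # -- parameter layout ----------------------------------------------------
    def detection_param_names(self, n_occasions: int) -> list[str]:
        names = ["g0"]
        if self.uses_t:
            names += [f"g0.t{k + 1}" for k in range(1, n_occasions)]
        if self.behavior:
            names.append(f"g0.{self.behavior}")
        if "sex" in self.g0_terms:
            names.append("g0.sexM")
        names.append("sigma")
        if "sex" in self.sigma_terms:
            names.append("sigma.sexM")
        return names

    def param_names(self, n_occasions: int) -> list[str]:
        names = ["D"] + self.detection_param_names(n_occasions)
        if self.uses_sex:
            names.append("psi")
        return names

    def n_params(self, n_occasions: int) -> int:
        return len(self.param_names(n_occasions))


@dataclass
class BehaviorCovariate:
    """Indicator tensor z[i, j, k] of prior-detection state.

    b:  detected anywhere on any earlier occasion (same for all j);
    bk: detected at detector j on any earlier occasion;
    Bk: detected at detector j on the immediately preceding occasion.
    Occasion 1 is always all-zero.
    """

    z: np.ndarray  # (n, J, K) in {0, 1}
    kind: str

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=np.uint8)
        if self.kind not in BEHAVIOR_TYPES:
            raise ValueError(f"unknown behaviour type {self.kind!r}")
        if self.z.size and self.z[:, :, 0].any():
            raise ValueError("behaviour state must be zero on occasion 1")


def halfnormal_p(d, g0, sigma):
    """Half-normal detection probability ``g0 * exp(-d^2 / (2 sigma^2))``."""
    d = np.asarray(d, dtype=float)
    g0 = np.asarray(g0, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    if np.any((g0 < 0) | (g0 > 1)):
        raise ValueError("g0 must lie in [0, 1]")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    return g0 * np.exp(-(d ** 2) / (2.0 * sigma ** 2))


def build_behavior_covariates(y: np.ndarray, kind: str) -> BehaviorCovariate:
    """Build the behavioural-state indicator tensor from detection histories.

    ``y`` may be a CaptureData or an (n, J, K) binary array.
    """
    y = np.asarray(getattr(y, "y", y), dtype=np.uint8)
    if kind not in BEHAVIOR_TYPES:
        raise ValueError(f"unknown behaviour type {kind!r} (expected one of {BEHAVIOR_TYPES})")
    n, J, K = y.shape
    z = np.zeros_like(y)
    if kind == "b":
        seen = np.cumsum(y.any(axis=1), axis=1) > 0  # (n, K): detected by occasion k
        z[:, :, 1:] = seen[:, None, :-1]
    elif kind == "bk":
        cum = np.cumsum(y, axis=2) > 0  # detected at j by occasion k
        z[:, :, 1:] = cum[:, :, :-1]
    else:  # Bk
        z[:, :, 1:] = y[:, :, :-1]
    return BehaviorCovariate(z, kind)


@dataclass
class DetectionProbabilities:
    """Dense per-animal and naive detection-probability tensors.

    ``p[i, s, j, k]`` is animal *i*'s detection probability at source point
    *s* (a mask point or trap), detector *j*, occasion *k* given its own
    behavioural state and sex class.  ``naive[c]`` holds the pre-response
    probabilities for sex class ``c`` (``None`` key when the model is
    sexless), used for the undetected-animal component of the likelihood.

    Dense tensors are intended for small instances (testing, small masks);
    the likelihood machinery itself uses an equivalent factored form.
    """

    p: np.ndarray                 # (n, S, J, K)
    naive: dict                   # class -> (S, J, K)
    sigma: dict                   # class -> float


def _g0_eta(spec: ModelSpec, beta: np.ndarray, n_occasions: int):
    """Split a detection beta vector into named pieces."""
    names = spec.detection_param_names(n_occasions)
    if len(beta) != len(names):
        raise ValueError(
            f"beta has length {len(beta)}, expected {len(names)} ({names})"
        )
    vals = dict(zip(names, beta))
    t_effects = np.zeros(n_occasions)
    if spec.uses_t:
        for k in range(1, n_occasions):
            t_effects[k] = vals[f"g0.t{k + 1}"]
    return vals, t_effects


def detection_probabilities(
    spec: ModelSpec,
    beta: np.ndarray,
    distances: np.ndarray,
    behavior: Optional[BehaviorCovariate] = None,
    sex: Optional[np.ndarray] = None,
    n_occasions: Optional[int] = None,
) -> DetectionProbabilities:
    """Materialise detection probabilities for every animal and source point.

    ``distances`` is an (S, J) matrix from S source points (mask points or
    activity-center candidates) to J detectors.  ``behavior`` must be given
    for behavioural models, ``sex`` (codes F/M/U) for sex models.
    """
    beta = np.asarray(beta, dtype=float)
    distances = np.asarray(distances, dtype=float)
    if behavior is not None:
        n, J, K = behavior.z.shape
    else:
        n = len(sex) if sex is not None else 1
        J = distances.shape[1]
        if n_occasions is None:
            raise ValueError("n_occasions required when no behaviour tensor is given")
        K = n_occasions
    if n_occasions is not None and behavior is not None and behavior.z.shape[2] != n_occasions:
        raise ValueError("behaviour tensor and n_occasions disagree")
    vals, t_eff = _g0_eta(spec, beta, K)
    S = distances.shape[0]
    d2 = distances ** 2

    classes = (0, 1) if spec.uses_sex else (None,)
    sigma_by_class = {}
    for c in classes:
        log_sigma = vals["sigma"] + (vals.get("sigma.sexM", 0.0) * c if c else 0.0)
        sigma_by_class[c] = float(np.exp(log_sigma))

    def eta_g0(c, z):
        e = vals["g0"] + t_eff  # (K,)
        if spec.behavior:
            e = e + vals[f"g0.{spec.behavior}"] * z  # broadcast over z
        if "sex" in spec.g0_terms and c:
            e = e + vals["g0.sexM"]
        return e

    naive = {}
    for c in classes:
        kern = np.exp(-d2 / (2.0 * sigma_by_class[c] ** 2))  # (S, J)
        g0 = expit(eta_g0(c, np.zeros(K)))                   # (K,)
        naive[c] = kern[:, :, None] * g0[None, None, :]

    if spec.uses_sex and sex is None:
        raise ValueError("sex codes required for a sex model")
    sex_code = np.zeros(n, dtype=int)
    if sex is not None:
        sex_code = np.array([1 if s == "M" else 0 for s in sex])

    p = np.empty((n, S, J, K))
    for i in range(n):
        c = sex_code[i] if spec.uses_sex else None
        kern = np.exp(-d2 / (2.0 * sigma_by_class[c] ** 2))
        if spec.behavior:
            z_i = behavior.z[i].astype(float)  # (J, K)
            eta = vals["g0"] + t_eff[None, :] + vals[f"g0.{spec.behavior}"] * z_i
            if "sex" in spec.g0_terms and c:
                eta = eta + vals["g0.sexM"]
            p[i] = kern[:, :, None] * expit(eta)[None, :, :]
        else:
            p[i] = naive[c]
    return DetectionProbabilities(p=p, naive=naive, sigma=sigma_by_class)


def to_link(value, link: str):
    """Map a natural-scale parameter to its link scale."""
    if link == "logit":
        return logit(value)
    if link == "log":
        return np.log(value)
    raise ValueError(f"unknown link {link!r}")


def from_link(value, link: str):
    """Inverse of :func:`to_link`."""
    if link == "logit":
        return expit(value)
    if link == "log":
        return np.exp(value)
    raise ValueError(f"unknown link {link!r}")
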