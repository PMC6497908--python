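"""Epoch averaging, corrective-response deltas, and the structure regression.

A corrective response is the change in the stride-averaged activity
vector across a sudden belt-speed transition:

    dEMG = EMG_after - EMG_before

The structure of the response to removing the split environment is
quantified with a two-factor regression through the origin,

    dEMG_off(+) = -beta_no_adapt * dEMG_on(+) + beta_adapt * dEMG_on(-)

where dEMG_on(-) — the response to introducing the mirror-image split
environment — is inferred by transposing the two legs' activity in
dEMG_on(+).  beta_no_adapt = 1, beta_adapt = 0 is a purely
environment-based response (off = numerical opposite of on);
beta_no_adapt = 0, beta_adapt = 1 is a fully adapted response (off =
response to the opposite perturbation).  Goodness of fit uses the
uncentered R^2 = 1 - sum(r^2)/sum(y^2), appropriate for a model without
intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .vectors import ActivityIndex, DEFAULT_INDEX


class UndefinedCosineError(ValueError):
    """Cosine requested with a zero vector."""


class CollinearFactorsError(ValueError):
    """Regression factors too close to collinear to separate."""


class InsufficientStridesError(ValueError):
    """A condition with too few strides for the requested epoch."""


@dataclass(frozen=True)
class EpochSpec:
    """Rule mapping a condition's stride sequence to one averaged vector.

    The very first and last stride of every condition are excluded (they
    are contaminated by the treadmill starting/stopping): ``early`` is
    the mean of the first ``n_strides`` after dropping stride 1 (so the
    default early epoch is strides 2-6); ``late`` the mean of the last
    ``n_strides`` after dropping the final stride; ``whole`` the mean of
    everything after dropping both.
    """

    condition: str
    mode: str = "early"  # early | late | whole
    n_strides: int = 5

    def __post_init__(self) -> None:
        if self.mode not in ("early", "late", "whole"):
            raise ValueError(f"unknown epoch mode {self.mode!r}")
        if self.n_strides < 1:
            raise ValueError("n_strides must be >= 1")


EARLY = lambda cond, n=5: EpochSpec(cond, "early", n)  # noqa: E731
LATE = lambda cond, n=40: EpochSpec(cond, "late", n)  # noqa: E731
WHOLE = lambda cond: EpochSpec(cond, "whole")  # noqa: E731


def epoch_vector(stride_vectors: np.ndarray, spec: EpochSpec) -> np.ndarray:
    """Component-wise mean over the epoch's stride window.

    ``stride_vectors`` holds all strides of the condition in order,
    including the first and last (the exclusions are applied here).
    """
    v = np.asarray(stride_vectors, float)
    n = v.shape[0]
    if spec.mode == "early":
        need = spec.n_strides + 1
        if n < need:
            raise InsufficientStridesError(
                f"{spec.condition}: early epoch needs {need} strides, have {n}"
            )
        win = v[1 : 1 + spec.n_strides]
    elif spec.mode == "late":
        need = spec.n_strides + 1
        if n < need:
            raise InsufficientStridesError(
                f"{spec.condition}: late epoch needs {need} strides, have {n}"
            )
        win = v[-1 - spec.n_strides : -1]
    else:  # whole
        if n < 3:
            raise InsufficientStridesError(
                f"{spec.condition}: whole epoch needs >= 3 strides, have {n}"
            )
        win = v[1:-1]
    return win.mean(axis=0)


@dataclass
class DeltaResponse:
    """Difference of two epoch vectors, labelled by transition."""

    values: np.ndarray
    label: str
    index: ActivityIndex = field(default_factory=lambda: DEFAULT_INDEX)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.label}: non-finite delta components")


def delta_response(
    after: np.ndarray,
    before: np.ndarray,
    label: str,
    index: ActivityIndex = DEFAULT_INDEX,
    provenance: dict | None = None,
) -> DeltaResponse:
    """Corrective response ``after - before`` (component-wise)."""
    after = np.asarray(after, float)
    before = np.asarray(before, float)
    if after.shape != before.shape:
        raise ValueError(f"shape mismatch {after.shape} vs {before.shape}")
    return DeltaResponse(after - before, label, index, provenance or {})


def mirror_transpose(d: DeltaResponse) -> DeltaResponse:
    """Leg-transposed response: the inferred on(-) factor.

    Exchanges the slow- and fast-leg blocks, preserving (muscle, phase)
    order within each block; values are unchanged, so this is a
    norm-preserving involution.
    """
    if d.values.shape[-1] != d.index.n_components:
        raise ValueError("vector length inconsistent with its ActivityIndex")
    return DeltaResponse(
        d.index.mirror(d.values),
        label=f"mirror({d.label})",
        index=d.index,
        provenance=dict(d.provenance, mirrored=True),
    )


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two activity vectors."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise UndefinedCosineError("cosine undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


def vector_magnitude(v: np.ndarray) -> float:
    """Euclidean norm of an activity vector."""
    v = np.asarray(v, float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite components")
    return float(np.linalg.norm(v))


def collinearity_check(d_on_plus: DeltaResponse) -> float:
    """Cosine between the inferred on(-) factor and -on(+).

    The regression can only separate its two factors when this is well
    below 1 in magnitude; it equals 1 exactly when the on(+) response is
    anti-symmetric across legs (mirror(d) = -d) and -1 when it is
    symmetric.
    """
    return cosine(mirror_transpose(d_on_plus).values, -d_on_plus.values)


@dataclass
class RegressionResult:
    """Fitted structure regression for one off-transition."""

    beta_adapt: float
    beta_no_adapt: float
    ci_adapt: tuple[float, float]
    ci_no_adapt: tuple[float, float]
    r2_uncentered: float
    residuals: np.ndarray
    n_observations: int
    level: str = "subject"
    collinearity_cos: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "beta_adapt": self.beta_adapt,
            "beta_no_adapt": self.beta_no_adapt,
            "ci_adapt": list(self.ci_adapt),
            "ci_no_adapt": list(self.ci_no_adapt),
            "r2_uncentered": self.r2_uncentered,
            "n_observations": self.n_observations,
            "level": self.level,
            "collinearity_cos": self.collinearity_cos,
        }


def fit_structure(
    d_off: DeltaResponse,
    d_on_plus: DeltaResponse,
    d_on_minus: DeltaResponse | None = None,
    level: str = "subject",
    collinearity_limit: float = 0.99,
) -> RegressionResult:
    """Ordinary least squares of the off-response on the two factors.

    The design matrix is ``[-d_on_plus, d_on_minus]`` with no intercept,
    so beta_no_adapt (the coefficient on the first column) equals +1
    when the off-response is the exact numerical opposite of the
    on-response.  If ``d_on_minus`` is omitted it is inferred by leg
    transposition of ``d_on_plus``.  Confidence intervals are the
    normal-theory 95% OLS intervals with n - 2 residual degrees of
    freedom, treating the vector components as observations.
    """
    if d_on_minus is None:
        d_on_minus = mirror_transpose(d_on_plus)
    y = d_off.values.ravel()
    f1 = d_on_plus.values.ravel()
    f2 = d_on_minus.values.ravel()
    if not (y.shape == f1.shape == f2.shape):
        raise ValueError("response and factors must have identical indexing")
    ccos = cosine(f2, -f1)
    if abs(ccos) >= collinearity_limit:
        raise CollinearFactorsError(
            f"|cos(on(-), -on(+))| = {abs(ccos):.3f} >= {collinearity_limit}: "
            "factors too collinear to separate"
        )
    X = np.column_stack([-f1, f2])
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    ssy = float(np.sum(y**2))
    r2 = 1.0 - float(np.sum(fit.resid**2)) / ssy if ssy > 0 else float("nan")
    return RegressionResult(
        beta_adapt=float(fit.params[1]),
        beta_no_adapt=float(fit.params[0]),
        ci_adapt=(float(ci[1, 0]), float(ci[1, 1])),
        ci_no_adapt=(float(ci[0, 0]), float(ci[0, 1])),
        r2_uncentered=r2,
        residuals=np.asarray(fit.resid),
        n_observations=y.size,
        level=level,
        collinearity_cos=ccos,
    )
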