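"""Group comparison: normality, t-test matrices, DID, centroids/distances.

Works on a :class:`~erdspec.io.FeatureSet` of deep-spectrum vectors labeled
by group (tinnitus/control) and session (S1 before / S2 after treatment).

* Per-instance scalar outcome Y (default: mean of the 1280 features).
* Lilliefors normality test with seeded Monte-Carlo p-values.
* Two-sample Student's t (pooled variance) with the +/- coding used in the
  comparison matrices: "+" marks p > 0.05 (statistically significant
  relationship), "-" marks p < 0.05 (significant difference).
* Difference-in-differences estimator
  Y = b0 + b1*Time + b2*Intervention + b3*(Time*Intervention) + e,
  where b3 > 0 is read as a positive treatment effect.
* Centroids C_i = (1/p) sum_j x_ij, per-instance Euclidean distances to a
  reference centroid, and their mean / population standard deviation
  (denominator N).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import FeatureSet

__all__ = [
    "Centroid",
    "DistanceSummary",
    "DIDResult",
    "ComparisonMatrix",
    "scalar_outcome",
    "lilliefors_test",
    "t_test",
    "comparison_matrix",
    "did_estimate",
    "centroid",
    "distance_summary",
    "distance_table",
    "boxplot_summary",
]

ALPHA_DEFAULT = 0.05

# the six cohort-level pairings and the five per-subject pairings
WITHIN_PAIRINGS = [
    (("tinnitus", "S1"), ("control", "S1")),
    (("tinnitus", "S1"), ("control", "S2")),
    (("tinnitus", "S2"), ("control", "S1")),
    (("tinnitus", "S2"), ("control", "S2")),
    (("tinnitus", "S1"), ("tinnitus", "S2")),
    (("control", "S1"), ("control", "S2")),
]
BETWEEN_PAIRINGS = WITHIN_PAIRINGS[:5]


# ---------------------------------------------------------------------------
# scalar outcome


def scalar_outcome(
    features: FeatureSet,
    method: str = "mean_of_features",
    reference: "Centroid | None" = None,
    feature_index: int | None = None,
) -> np.ndarray:
    """Collapse each 1280-vector to the scalar Y used by t-tests and DID.

    ``mean_of_features`` (default) averages each vector's components;
    ``distance_to_centroid`` uses the Euclidean distance to ``reference``;
    ``single_feature`` picks component ``feature_index``.
    """
    if len(features) == 0:
        raise ValueError("empty feature set")
    if method == "mean_of_features":
        return features.vectors.mean(axis=1)
    if method == "distance_to_centroid":
        if reference is None:
            raise ValueError("distance_to_centroid needs a reference centroid")
        return np.linalg.norm(features.vectors - reference.C[None, :], axis=1)
    if method == "single_feature":
        if feature_index is None:
            raise ValueError("single_feature needs feature_index")
        return features.vectors[:, feature_index]
    raise ValueError(f"unknown outcome method {method!r}")


# ---------------------------------------------------------------------------
# Lilliefors normality test

_NULL_TABLE_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def _lilliefors_statistic(sample: np.ndarray) -> float:
    """max |ECDF - Normal(mean, sd) CDF| with parameters fitted to the sample."""
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    mu = x.mean()
    sd = x.std(ddof=1)
    if sd == 0:
        return 1.0
    cdf = stats.norm.cdf(x, loc=mu, scale=sd)
    upper = np.arange(1, n + 1) / n - cdf
    lower = cdf - np.arange(0, n) / n
    return float(max(upper.max(), lower.max()))


def _null_statistics(n: int, n_draws: int = 10_000, seed: int = 12345) -> np.ndarray:
    """Monte-Carlo null distribution of the statistic for sample size n (cached)."""
    key = (n, n_draws, seed)
    if key not in _NULL_TABLE_CACHE:
        rng = np.random.default_rng(seed)
        draws = rng.standard_normal((n_draws, n))
        draws.sort(axis=1)
        mu = draws.mean(axis=1, keepdims=True)
        sd = draws.std(axis=1, ddof=1, keepdims=True)
        grid = np.arange(1, n + 1) / n
        cdf = stats.norm.cdf((draws - mu) / sd)
        stat = np.maximum((grid - cdf).max(axis=1), (cdf - (grid - 1.0 / n)).max(axis=1))
        _NULL_TABLE_CACHE[key] = np.sort(stat)
    return _NULL_TABLE_CACHE[key]


def lilliefors_test(sample: np.ndarray, n_draws: int = 10_000, seed: int = 12345) -> tuple[float, float]:
    """Lilliefors test of composite normality.

    Returns ``(statistic, p_value)``; the p-value is the fraction of the
    seeded Monte-Carlo null distribution at or above the statistic.
    """
    x = np.asarray(sample, dtype=float).ravel()
    if x.size < 4:
        raise ValueError(f"Lilliefors test needs n >= 4, got n={x.size}")
    stat = _lilliefors_statistic(x)
    null = _null_statistics(x.size, n_draws=n_draws, seed=seed)
    p = float((null >= stat - 1e-15).mean())
    return stat, p


# ---------------------------------------------------------------------------
# Student's t with +/- coding


def t_test(a: np.ndarray, b: np.ndarray, alpha: float = ALPHA_DEFAULT) -> tuple[float, float, str]:
    """Two-sample Student's t-test (pooled variance).

    Returns ``(t, p, code)`` with code "+" iff p > alpha.  Two identical
    zero-variance samples yield p = 1 rather than an error.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, "+"
        return float(np.inf * np.sign(a.mean() - b.mean())), 0.0, "-"
    t, p = stats.ttest_ind(a, b, equal_var=True)
    code = "+" if p > alpha else "-"
    return float(t), float(p), code


@dataclass
class ComparisonMatrix:
    """Pairwise t-test results with the +/- significance coding."""

    table: pd.DataFrame  # columns: pairing (+ subject for between), t, p, code
    design: str
    alpha: float = ALPHA_DEFAULT


def _pairing_name(cell_a: tuple[str, str], cell_b: tuple[str, str]) -> str:
    fmt = lambda c: f"{c[0].capitalize()} {c[1]}"
    return f"{fmt(cell_a)}–{fmt(cell_b)}"


def comparison_matrix(
    features: FeatureSet,
    design: str = "within",
    outcome: str = "mean_of_features",
    alpha: float = ALPHA_DEFAULT,
) -> ComparisonMatrix:
    """Pairwise t-test matrix over the four group x session cells.

    ``within`` emits the six cohort-level pairings; ``between`` emits, for
    each tinnitus subject, the five pairings of that subject's instances
    against the pooled control instances (and the subject's own S1 vs S2).
    """
    y = scalar_outcome(features, method=outcome)
    labels = features.labels

    def cell_values(group: str, session: str, subject=None) -> np.ndarray:
        m = (labels["group"] == group) & (labels["session"] == session)
        if subject is not None:
            m &= labels["subject"] == subject
        return y[m.to_numpy()]

    rows = []
    if design == "within":
        for cell_a, cell_b in WITHIN_PAIRINGS:
            va, vb = cell_values(*cell_a), cell_values(*cell_b)
            for cell, v in ((cell_a, va), (cell_b, vb)):
                if v.size == 0:
                    raise ValueError(f"empty cell {cell} in feature set")
                if v.size < 2:
                    raise ValueError(f"cell {cell} has a single instance; t-test undefined")
            t, p, code = t_test(va, vb, alpha)
            rows.append({"pairing": _pairing_name(cell_a, cell_b), "t": t, "p": p, "code": code})
    elif design == "between":
        subjects = sorted(labels.loc[labels["group"] == "tinnitus", "subject"].unique())
        if not subjects:
            raise ValueError("no tinnitus subjects in feature set")
        for subj in subjects:
            for cell_a, cell_b in BETWEEN_PAIRINGS:
                va = cell_values(*cell_a, subject=subj)
                vb = cell_values(*cell_b, subject=subj) if cell_b[0] == "tinnitus" else cell_values(*cell_b)
                if va.size < 2 or vb.size < 2:
                    raise ValueError(
                        f"cell {cell_a} / {cell_b} too small for subject {subj}"
                    )
                t, p, code = t_test(va, vb, alpha)
                rows.append(
                    {"subject": subj, "pairing": _pairing_name(cell_a, cell_b),
                     "t": t, "p": p, "code": code}
                )
    else:
        raise ValueError(f"unknown design {design!r} (expected 'within' or 'between')")
    return ComparisonMatrix(table=pd.DataFrame(rows), design=design, alpha=alpha)


# ---------------------------------------------------------------------------
# difference in differences


@dataclass
class DIDResult:
    """OLS coefficients of the DID model and the qualitative effect label."""

    beta0: float  # baseline average (control, pre)
    beta1: float  # time trend in the control group
    beta2: float  # pre-intervention group difference
    beta3: float  # difference-in-differences estimator
    effect: str   # "Positive effect" iff beta3 > 0

    @property
    def betas(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2, self.beta3])


def did_estimate(y: np.ndarray, time: np.ndarray, group: np.ndarray) -> DIDResult:
    """Fit Y = b0 + b1*Time + b2*Intervention + b3*(Time*Intervention) by OLS.

    ``time``: 0 = S1 (pre), 1 = S2 (post); ``group``: 0 = control,
    1 = tinnitus (the intervention arm).  b3 equals the closed-form
    difference of cell-mean differences
    (mean_T,S2 - mean_T,S1) - (mean_C,S2 - mean_C,S1).
    """
    y = np.asarray(y, dtype=float).ravel()
    time = np.asarray(time).astype(float).ravel()
    group = np.asarray(group).astype(float).ravel()
    if not (y.size == time.size == group.size):
        raise ValueError("y, time, group must have equal length")
    for t_val in (0, 1):
        for g_val in (0, 1):
            if not np.any((time == t_val) & (group == g_val)):
                raise ValueError(f"empty design cell time={t_val}, group={g_val}")
    X = np.column_stack([np.ones_like(y), time, group, time * group])
    if np.linalg.matrix_rank(X) < 4:
        raise ValueError("degenerate (collinear) design matrix")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    b0, b1, b2, b3 = (float(v) for v in beta)
    effect = "Positive effect" if b3 > 0 else "Negative effect"
    return DIDResult(beta0=b0, beta1=b1, beta2=b2, beta3=b3, effect=effect)


# ---------------------------------------------------------------------------
# centroids and distances


@dataclass
class Centroid:
    """Coordinate-wise mean of one cell's feature vectors."""

    C: np.ndarray
    group: str = ""
    session: str = ""
    p: int = 0  # number of instances averaged


@dataclass
class DistanceSummary:
    """Euclidean distances to a reference centroid with mean and population SD."""

    distances: np.ndarray
    mean: float
    std: float  # population form, denominator N
    n: int


def centroid(vectors: np.ndarray, group: str = "", session: str = "") -> Centroid:
    """C_i = (1/p) sum_j x_ij over the cell's p instances."""
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    if vectors.shape[0] < 1 or vectors.size == 0:
        raise ValueError("centroid of an empty cell is undefined")
    return Centroid(C=vectors.mean(axis=0), group=group, session=session, p=vectors.shape[0])


def distance_summary(vectors: np.ndarray, ref: Centroid) -> DistanceSummary:
    """Per-instance Euclidean distance to ``ref``; mean and population SD."""
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    if vectors.shape[1] != ref.C.size:
        raise ValueError(
            f"dimension mismatch: vectors are {vectors.shape[1]}-D, centroid {ref.C.size}-D"
        )
    d = np.linalg.norm(vectors - ref.C[None, :], axis=1)
    return DistanceSummary(
        distances=d, mean=float(d.mean()), std=float(d.std(ddof=0)), n=d.size
    )


# the five instance-to-centroid pairings reported in the distance table
DISTANCE_PAIRINGS = [
    (("tinnitus", "S1"), ("control", "S1")),
    (("tinnitus", "S2"), ("control", "S1")),
    (("tinnitus", "S1"), ("control", "S2")),
    (("tinnitus", "S2"), ("control", "S2")),
    (("control", "S1"), ("control", "S2")),
]


def distance_table(features: FeatureSet) -> pd.DataFrame:
    """Mean/SD of distances from each cell's instances to control centroids.

    Five rows: tinnitus S1/S2 and control S1 instances against the control
    S1 and S2 centroids, mirroring the closeness analysis between treated
    patients and controls.
    """
    cents = {}
    for session in ("S1", "S2"):
        cell = features.cell("control", session)
        if cell.shape[0] == 0:
            raise ValueError(f"empty cell ('control', {session!r})")
        cents[session] = centroid(cell, "control", session)
    rows = []
    for (g_a, s_a), (g_b, s_b) in DISTANCE_PAIRINGS:
        inst = features.cell(g_a, s_a)
        if inst.shape[0] == 0:
            raise ValueError(f"empty cell ({g_a!r}, {s_a!r})")
        summ = distance_summary(inst, cents[s_b])
        rows.append(
            {
                "instances": f"{g_a.capitalize()} {s_a}",
                "centroid": f"{g_b.capitalize()} {s_b}",
                "mean": summ.mean,
                "std": summ.std,
                "n": summ.n,
            }
        )
    return pd.DataFrame(rows)


def boxplot_summary(features: FeatureSet, outcome: str = "mean_of_features") -> pd.DataFrame:
    """Five-number summary (min, Q1, median, Q3, max) of Y per study cell.

    Quartiles use linear interpolation between order statistics.
    """
    y = scalar_outcome(features, method=outcome)
    labels = features.labels
    rows = []
    for group in ("tinnitus", "control"):
        for session in ("S1", "S2"):
            m = ((labels["group"] == group) & (labels["session"] == session)).to_numpy()
            if not m.any():
                raise ValueError(f"empty cell ({group!r}, {session!r})")
            v = y[m]
            q = np.percentile(v, [0, 25, 50, 75, 100], method="linear")
            rows.append(
                {
                    "cell": f"{'T' if group == 'tinnitus' else 'C'}-{session}",
                    "min": q[0], "q1": q[1], "median": q[2], "q3": q[3], "max": q[4],
                    "n": int(m.sum()),
                }
            )
    return pd.DataFrame(rows)
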