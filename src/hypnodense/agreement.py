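"""Inter-scorer agreement statistics.

Implements pairwise agreement (Cohen's kappa, percent agreement), the
complete-agreement-versus-number-of-scorers curve with its power-law model
y = a * k**b, and the two metrics used to compare probability curves:
the intraclass correlation coefficient for absolute agreement, ICC(A,1),
and the average cosine similarity (ACS) between paired per-epoch
probability vectors.

The agreement curve averages, for each panel size k, the percentage of
epochs on which all k scorers agree, over scorer subsets of size k.
Averaging over unordered subsets equals averaging over ordered
permutations because epoch-wise complete agreement is order-invariant, so
enumeration over combinations is exact and exponentially cheaper.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.metrics import confusion_matrix

from .core import Hypnodensity, Hypnogram, ScorerPanel
from .errors import AlignmentError, HypnodensityError, UndefinedStatisticError

__all__ = [
    "cohens_kappa",
    "percent_agreement",
    "AgreementCurve",
    "agreement_curve",
    "PowerLawFit",
    "fit_power_law",
    "icc_absolute",
    "average_cosine_similarity",
    "ProbabilityCurveComparison",
    "compare_probability_curves",
    "koo_label",
]


def _check_aligned(a: Hypnogram, b: Hypnogram) -> None:
    if a.vocabulary != b.vocabulary:
        raise AlignmentError("hypnograms use different vocabularies")
    if a.n_epochs != b.n_epochs:
        raise AlignmentError(
            f"hypnograms have {a.n_epochs} and {b.n_epochs} epochs"
        )


def cohens_kappa(a: Hypnogram, b: Hypnogram) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    p_o is the observed fraction of identical epochs; p_e the agreement
    expected by chance from the two scorers' marginal stage frequencies.
    Unweighted (all stage disagreements count equally).

    Raises
    ------
    UndefinedStatisticError
        If p_e = 1 (both scorers constant with identical marginals), where
        the ratio is 0/0.
    """
    _check_aligned(a, b)
    labels = list(range(len(a.vocabulary)))
    cm = confusion_matrix(a.as_indices(), b.as_indices(), labels=labels)
    n = cm.sum()
    p_o = np.trace(cm) / n
    p_e = float((cm.sum(axis=1) / n) @ (cm.sum(axis=0) / n))
    if 1.0 - p_e < 1e-12:
        raise UndefinedStatisticError(
            "kappa undefined: expected agreement p_e = 1 (constant scorers)"
        )
    return float((p_o - p_e) / (1.0 - p_e))


def percent_agreement(a: Hypnogram, b: Hypnogram) -> float:
    """Percentage of epochs with identical labels."""
    _check_aligned(a, b)
    same = sum(x == y for x, y in zip(a.stages, b.stages))
    return 100.0 * same / a.n_epochs


@dataclass(frozen=True)
class AgreementCurve:
    """Mean complete-agreement percentage as a function of panel size k.

    ``exact[i]`` records whether the value at ``k[i]`` was obtained by full
    subset enumeration or by seeded Monte Carlo subsampling.
    """

    k: np.ndarray
    mean_complete_agreement: np.ndarray
    n_subsets_evaluated: np.ndarray
    exact: np.ndarray

    def __post_init__(self) -> None:
        for name in ("k", "mean_complete_agreement", "n_subsets_evaluated", "exact"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        y = self.mean_complete_agreement
        if np.any(y < 0) or np.any(y > 100):
            raise HypnodensityError("agreement percentages must lie in [0, 100]")


def agreement_curve(
    panel: ScorerPanel, max_subsets: int = 10_000, seed: int | None = None
) -> AgreementCurve:
    """Complete-agreement percentage averaged over scorer subsets of each size.

    For each k in 1..n_scorers: the percentage of epochs on which all k
    scorers agree, averaged over subsets of size k.  Full enumeration when
    C(n, k) <= ``max_subsets``; otherwise ``max_subsets`` subsets are drawn
    with a seeded generator and the ``exact`` flag is cleared.
    """
    if panel.n_scorers < 2:
        raise AlignmentError("agreement curve requires at least two scorers")
    labels = panel.to_index_matrix()
    n = panel.n_scorers
    rng = np.random.default_rng(seed)

    ks, means, counts, exact = [], [], [], []
    for k in range(1, n + 1):
        n_comb = math.comb(n, k)
        if k == 1:
            subsets: list[tuple[int, ...]] = [(j,) for j in range(n)]
            is_exact = True
        elif n_comb <= max_subsets:
            subsets = list(itertools.combinations(range(n), k))
            is_exact = True
        else:
            subsets = [
                tuple(rng.choice(n, size=k, replace=False))
                for _ in range(max_subsets)
            ]
            is_exact = False
        vals = [
            100.0 * float((labels[list(s)] == labels[s[0]]).all(axis=0).mean())
            for s in subsets
        ]
        ks.append(k)
        means.append(float(np.mean(vals)))
        counts.append(len(subsets))
        exact.append(is_exact)
    return AgreementCurve(
        np.array(ks), np.array(means), np.array(counts), np.array(exact)
    )


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares fit of y = a * k**b to an agreement curve.

    ``a`` is the coefficient in percent (the level at k = 1), ``b`` the
    dimensionless decay exponent; an exponent near -0.5 means complete
    agreement falls roughly with the square root of the panel size.
    ``r_squared`` is 1 - SS_res/SS_tot on the raw (percent) scale.
    """

    a: float
    b: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise HypnodensityError("power-law coefficient must be positive")

    def predict(self, k) -> np.ndarray:
        return self.a * np.asarray(k, dtype=float) ** self.b


def fit_power_law(curve: AgreementCurve) -> PowerLawFit:
    """Fit y = a * k**b by nonlinear least squares on the raw scale.

    Initialized from the ordinary least-squares solution in log-log space;
    R^2 is reported on the raw scale.  Requires at least three distinct k
    values and strictly positive agreement percentages (the log-space
    initialization is otherwise impossible).
    """
    x = np.asarray(curve.k, dtype=float)
    y = np.asarray(curve.mean_complete_agreement, dtype=float)
    if np.unique(x).size < 3:
        raise HypnodensityError("power-law fit requires at least 3 distinct k values")
    if np.any(y <= 0):
        raise HypnodensityError("power-law fit requires positive agreement values")
    b0, log_a0 = np.polyfit(np.log(x), np.log(y), 1)
    (a, b), _ = curve_fit(
        lambda k, a, b: a * k**b, x, y, p0=(math.exp(log_a0), b0), maxfev=10_000
    )
    resid = y - a * x**b
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(float(a), float(b), r2)


def _icc_a1(data: np.ndarray) -> float:
    """ICC(A,1): two-way random effects, single rater, absolute agreement.

    ``data`` is an (n subjects x k raters) matrix.  Computed from the
    two-way ANOVA mean squares (rows = subjects, columns = raters):

        ICC(A,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))
    """
    X = np.asarray(data, dtype=float)
    n, k = X.shape
    if n < 3:
        raise HypnodensityError("ICC requires at least 3 subjects (epochs)")
    gm = X.mean()
    ss_rows = k * float(((X.mean(axis=1) - gm) ** 2).sum())
    ss_cols = n * float(((X.mean(axis=0) - gm) ** 2).sum())
    ss_tot = float(((X - gm) ** 2).sum())
    ss_err = ss_tot - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if abs(denom) < 1e-15:
        raise UndefinedStatisticError(
            "ICC undefined: zero between-subject and residual variance"
        )
    return float((ms_r - ms_e) / denom)


def icc_absolute(series_a, series_b) -> float:
    """ICC for absolute agreement between two paired series (McGraw-Wong A,1).

    Treats the elements (epochs) as subjects and the two series as raters.
    Unlike a plain correlation, absolute agreement penalizes systematic
    offsets between the series.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise AlignmentError("series must be 1-D and of equal length")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise UndefinedStatisticError("ICC undefined: both series constant")
    return _icc_a1(np.column_stack([a, b]))


def average_cosine_similarity(ha: Hypnodensity, hb: Hypnodensity) -> float:
    """Mean over epochs of the cosine between paired probability rows.

    1.0 for identical hypnodensities; 0.0 when the per-epoch distributions
    put mass on disjoint stages everywhere.
    """
    if ha.vocabulary != hb.vocabulary:
        raise AlignmentError("hypnodensities use different vocabularies")
    if ha.n_epochs != hb.n_epochs:
        raise AlignmentError("hypnodensities are not epoch-aligned")
    na = np.linalg.norm(ha.probs, axis=1)
    nb = np.linalg.norm(hb.probs, axis=1)
    if np.any(na == 0) or np.any(nb == 0):
        raise HypnodensityError("all-zero probability row")
    cos = np.einsum("ij,ij->i", ha.probs, hb.probs) / (na * nb)
    return float(cos.mean())


def koo_label(icc: float) -> str:
    """Qualitative ICC band (annotation only): poor/moderate/good/excellent."""
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.9:
        return "good"
    return "excellent"


@dataclass(frozen=True)
class ProbabilityCurveComparison:
    """ICC and ACS comparison between two hypnodensities.

    ``icc_overall`` is the micro average: ICC(A,1) on the per-stage
    probability curves concatenated into one long series pair.
    """

    icc_per_stage: dict[str, float]
    icc_overall: float
    acs: float

    @property
    def icc_macro(self) -> float:
        """Unweighted mean of the per-stage ICCs."""
        return float(np.mean(list(self.icc_per_stage.values())))

    def labelled(self) -> dict[str, str]:
        out = {s: koo_label(v) for s, v in self.icc_per_stage.items()}
        out["overall"] = koo_label(self.icc_overall)
        return out


def compare_probability_curves(
    ha: Hypnodensity, hb: Hypnodensity
) -> ProbabilityCurveComparison:
    """Per-stage and overall ICC(A,1) plus ACS between two hypnodensities."""
    if ha.vocabulary != hb.vocabulary:
        raise AlignmentError("hypnodensities use different vocabularies")
    if ha.n_epochs != hb.n_epochs:
        raise AlignmentError("hypnodensities are not epoch-aligned")
    per_stage = {
        s: icc_absolute(ha.probs[:, i], hb.probs[:, i])
        for i, s in enumerate(ha.vocabulary.stages)
    }
    micro = icc_absolute(ha.probs.ravel(order="F"), hb.probs.ravel(order="F"))
    acs = average_cosine_similarity(ha, hb)
    return ProbabilityCurveComparison(per_stage, micro, acs)
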