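"""Design-based accuracy assessment and map summaries.

The published validation design: three strata from agreement with three
other oil-palm maps (all agree on presence / all agree on absence /
any disagreement), validation points allocated 25% / 25% / 50% to those
strata, each point labelled by 5-8 independent raters with a consensus
kept only at >= 80% agreement. Accuracy is then estimated with the
standard design-based stratified estimators: with stratum weights W_i
(area shares) and within-stratum confusion counts n_ij,

    p_ij = W_i * n_ij / n_i.          (cell proportions, map x reference)
    OA   = sum_j p_jj
    UA_c = p_cc / p_c.   (commission complement, of mapped class c)
    PA_c = p_cc / p_.c   (omission complement, of reference class c)
    V(OA) = sum_i W_i^2 * a_i (1 - a_i) / (n_i - 1),   a_i = stratum
            agreement rate;  95% CI = OA +/- 1.96 sqrt(V).

Because the strata are agreement strata, not map classes, UA/PA standard
errors use the stratified ratio-estimator (Taylor) variance, which
reduces to the formula above when the denominator is constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import GridMismatchError
from .synthetic import ConfigurationError

__all__ = [
    "STRATUM_NAMES",
    "StrataDefinition",
    "ValidationPoint",
    "AccuracyReport",
    "build_strata",
    "design_sample",
    "largest_remainder_allocation",
    "consensus_label",
    "simulate_raters",
    "stratified_accuracy",
    "summarize_extent_by_period",
]

STRATUM_NAMES = ("agree_presence", "agree_absence", "disagree")
AGREE_PRESENCE, AGREE_ABSENCE, DISAGREE = 0, 1, 2
_Z95 = 1.959963984540054


@dataclass
class StrataDefinition:
    stratum_raster: np.ndarray        # int8, values 0/1/2
    weights: np.ndarray               # (3,) pixel-count shares, sum 1
    counts: np.ndarray                # (3,) pixel counts

    def __post_init__(self) -> None:
        if abs(float(self.weights.sum()) - 1.0) > 1e-9:
            raise ValueError("stratum weights must sum to 1")


@dataclass
class ValidationPoint:
    row: int
    col: int
    stratum: int
    map_label: int                    # 0 / 1
    votes: list = field(default_factory=list)   # entries in {palm, not_palm, maybe}
    consensus: int | None = None      # 0 / 1, None = discarded
    true_label: int | None = None     # known only for synthetic scenes


@dataclass
class AccuracyReport:
    overall_accuracy: float
    overall_se: float
    ci_low: float
    ci_high: float
    users_accuracy: dict
    users_se: dict
    producers_accuracy: dict
    producers_se: dict
    confusion: np.ndarray             # (n_strata, 2, 2) counts, map x reference
    weights: np.ndarray
    n_per_stratum: np.ndarray
    estimator: str = "design-based stratified (ratio-estimator variances)"


def build_strata(map_a: np.ndarray, map_b: np.ndarray,
                 map_c: np.ndarray) -> StrataDefinition:
    """Three agreement strata from three binary oil-palm maps."""
    a, b, c = (np.asarray(m) for m in (map_a, map_b, map_c))
    if not (a.shape == b.shape == c.shape):
        raise GridMismatchError("the three maps must share one grid")
    s = np.full(a.shape, DISAGREE, np.int8)
    s[(a == 1) & (b == 1) & (c == 1)] = AGREE_PRESENCE
    s[(a == 0) & (b == 0) & (c == 0)] = AGREE_ABSENCE
    counts = np.array([(s == i).sum() for i in range(3)], np.int64)
    return StrataDefinition(s, counts / counts.sum(), counts)


def largest_remainder_allocation(n_total: int, fractions) -> np.ndarray:
    """Integer per-stratum sample sizes preserving the exact total.

    Floors the quotas then hands the remaining units to the largest
    fractional remainders (ties resolved by stratum order)."""
    fractions = np.asarray(fractions, float)
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ConfigurationError("allocation fractions must sum to 1")
    quota = fractions * n_total
    out = np.floor(quota).astype(int)
    order = np.argsort(-(quota - out), kind="stable")
    out[order[:n_total - out.sum()]] += 1
    return out


def design_sample(strata: StrataDefinition, n_total: int,
                  allocation=(0.25, 0.25, 0.50), seed: int = 0
                  ) -> list[ValidationPoint]:
    """Stratified random sample of validation point locations.

    Default allocation is the published 25% / 25% / 50% design over
    (agree-presence, agree-absence, disagree); sampling is uniform
    without replacement within each stratum.
    """
    per_stratum = largest_remainder_allocation(n_total, allocation)
    rng = np.random.default_rng(seed)
    rows, cols = strata.stratum_raster.shape
    points = []
    for s, n_s in enumerate(per_stratum):
        if n_s == 0:
            continue
        idx = np.flatnonzero(strata.stratum_raster.ravel() == s)
        if idx.size < n_s:
            raise ConfigurationError(
                f"stratum {STRATUM_NAMES[s]} has {idx.size} pixels, "
                f"cannot place {n_s} points")
        chosen = rng.choice(idx, size=n_s, replace=False)
        for flat in chosen:
            r, c = divmod(int(flat), cols)
            points.append(ValidationPoint(r, c, s, map_label=-1))
    return points


def consensus_label(votes: list[str], min_agreement: float = 0.8,
                    min_raters: int = 5, count_maybe_as_disagreement: bool = False):
    """Consensus of rater votes, or None when the point is discarded.

    Agreement is the largest class share among palm / not_palm votes
    ("maybe" is excluded from the denominator unless configured to count
    as disagreement). A point is kept only with >= ``min_raters`` votes
    (5-8 in the published campaign) and agreement >= ``min_agreement``
    (80%, inclusive).
    """
    if not votes:
        raise ConfigurationError("consensus_label needs at least one vote")
    if len(votes) < min_raters:
        return None
    n_palm = sum(v == "palm" for v in votes)
    n_not = sum(v == "not_palm" for v in votes)
    denom = len(votes) if count_maybe_as_disagreement else (n_palm + n_not)
    if denom == 0:
        return None
    top = max(n_palm, n_not)
    if n_palm == n_not or top / denom < min_agreement:
        return None
    return 1 if n_palm > n_not else 0


def simulate_raters(true_label: int, n_raters: int, error_rate: float = 0.1,
                    maybe_rate: float = 0.05, rng=None) -> list[str]:
    """Synthetic citizen-science votes: each rater flips the true label
    with ``error_rate`` and answers "maybe" with ``maybe_rate``."""
    rng = np.random.default_rng(rng)
    votes = []
    for _ in range(n_raters):
        if rng.random() < maybe_rate:
            votes.append("maybe")
            continue
        label = true_label if rng.random() >= error_rate else 1 - true_label
        votes.append("palm" if label == 1 else "not_palm")
    return votes


def _ratio_se(y: np.ndarray, x: np.ndarray, stratum: np.ndarray,
              weights: np.ndarray) -> tuple[float, float]:
    """Stratified ratio estimator R = Y/X and its Taylor-series SE.

    y, x are per-point indicator variables; strata index into weights.
    With x identically 1 this reduces to the stratified mean and the
    textbook V = sum W_i^2 s_i^2 / n_i = sum W_i^2 a_i(1-a_i)/(n_i-1).
    """
    ybar = xbar = 0.0
    used = []
    for s, w in enumerate(weights):
        m = stratum == s
        n_s = int(m.sum())
        if n_s == 0:
            continue
        used.append((s, w, m, n_s))
        ybar += w * y[m].mean()
        xbar += w * x[m].mean()
    if xbar == 0:
        return np.nan, np.nan
    r = ybar / xbar
    var = 0.0
    for s, w, m, n_s in used:
        if n_s < 2:
            continue
        d = y[m] - r * x[m]
        var += w ** 2 * d.var(ddof=1) / n_s
    return r, float(np.sqrt(var) / xbar)


def stratified_accuracy(points: list[ValidationPoint],
                        strata: StrataDefinition) -> AccuracyReport:
    """Design-based accuracy report from consensus-labelled points.

    Discarded points (no consensus) are ignored; strata with fewer than
    two retained points are excluded from estimation with a warning in
    the report's weights renormalization. Raises when nothing is left.
    """
    kept = [p for p in points if p.consensus is not None]
    if not kept:
        raise ConfigurationError("no retained validation points")
    stratum = np.array([p.stratum for p in kept])
    map_lab = np.array([p.map_label for p in kept])
    ref_lab = np.array([p.consensus for p in kept])
    if np.any(map_lab < 0):
        raise ValueError("validation points lack map labels")

    n_strata = len(strata.weights)
    n_per = np.array([(stratum == s).sum() for s in range(n_strata)])
    usable = n_per >= 2
    if not usable.all():
        keep_mask = usable[stratum]
        stratum, map_lab, ref_lab = stratum[keep_mask], map_lab[keep_mask], ref_lab[keep_mask]
        n_per = np.array([(stratum == s).sum() for s in range(n_strata)])
    weights = strata.weights * usable
    wsum = weights.sum()
    if wsum == 0:
        raise ConfigurationError("no stratum has >= 2 retained points")
    weights = weights / wsum

    confusion = np.zeros((n_strata, 2, 2), np.int64)
    for s in range(n_strata):
        m = stratum == s
        for i in (0, 1):
            for j in (0, 1):
                confusion[s, i, j] = int(((map_lab == i) & (ref_lab == j) & m).sum())

    agree = (map_lab == ref_lab).astype(float)
    oa, oa_se = _ratio_se(agree, np.ones_like(agree), stratum, weights)

    ua, ua_se, pa, pa_se = {}, {}, {}, {}
    for c, name in ((1, "oil_palm"), (0, "not_palm")):
        correct = ((map_lab == c) & (ref_lab == c)).astype(float)
        ua[name], ua_se[name] = _ratio_se(correct, (map_lab == c).astype(float),
                                          stratum, weights)
        pa[name], pa_se[name] = _ratio_se(correct, (ref_lab == c).astype(float),
                                          stratum, weights)

    return AccuracyReport(
        overall_accuracy=oa, overall_se=oa_se,
        ci_low=oa - _Z95 * oa_se, ci_high=oa + _Z95 * oa_se,
        users_accuracy=ua, users_se=ua_se,
        producers_accuracy=pa, producers_se=pa_se,
        confusion=confusion, weights=weights, n_per_stratum=n_per)


def summarize_extent_by_period(age_codes: np.ndarray,
                               region_masks: dict | None = None,
                               pixel_area_m2: float = 900.0,
                               archive_start: int = 1984,
                               map_year: int = 2017) -> pd.DataFrame:
    """Extent and detection-period shares per region.

    Periods follow the published summary: detected before 2000, 2000-2009
    and 2010 through the map year (codes < 20, 20-29, 30+ under the
    default 1984 encoding). Shares are over mapped palm pixels (codes >=
    4) and sum to 100% per region; NoData contributes nothing.
    """
    age_codes = np.asarray(age_codes)
    if region_masks is None:
        region_masks = {"all": np.ones(age_codes.shape, bool)}
    offset = archive_start - 4   # code 4 <-> archive start year
    c2000 = 2000 - offset
    c2010 = 2010 - offset
    rows = []
    for name, mask in region_masks.items():
        mask = np.asarray(mask, bool)
        if mask.shape != age_codes.shape:
            raise GridMismatchError(f"region mask {name!r} is off-grid")
        codes = age_codes[mask]
        palm = codes >= 4
        n_palm = int(palm.sum())
        shares = [np.nan] * 3
        if n_palm:
            shares = [
                100.0 * np.mean(codes[palm] < c2000),
                100.0 * np.mean((codes[palm] >= c2000) & (codes[palm] < c2010)),
                100.0 * np.mean(codes[palm] >= c2010),
            ]
        rows.append({
            "region": name,
            "palm_pixels": n_palm,
            "palm_area_ha": n_palm * pixel_area_m2 / 10_000.0,
            "detected_before_2000_pct": shares[0],
            "detected_2000_2009_pct": shares[1],
            f"detected_2010_{map_year}_pct": shares[2],
        })
    return pd.DataFrame(rows)
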