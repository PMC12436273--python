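"""Paired differential-metabolite testing, pathway DA scores and
metabolite-flux aggregation.

The paired Wilcoxon signed-rank test is exact for small samples: the
null distribution of the positive-rank sum is enumerated by dynamic
programming over the (doubled, hence integral) ranks, conditioning on
the observed |difference| ranks, which also makes the enumeration valid
under ties. The pathway differential-abundance (DA) score is
``(n_up - n_down) / n_measured`` over a pathway's measured members, in
[-1, 1]. Metabolite-level flux is the matrix product of a cell-type x
reaction flux matrix with a signed reaction x metabolite stoichiometric
matrix: positive entries mean net accumulation, negative net consumption.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from ._utils import benjamini_hochberg

logger = logging.getLogger(__name__)

EXACT_N_MAX = 25
COMPARTMENTS = ("[c]", "[e]", "[m]", "[l]", "[g]")


@dataclass
class PairedMetaboliteTable:
    """Tumor and normal intensity tables, metabolites x patients, paired
    by column position."""

    tumor: pd.DataFrame
    normal: pd.DataFrame

    def __post_init__(self) -> None:
        if self.tumor.shape != self.normal.shape:
            raise ValueError("tumor and normal tables differ in shape")
        if not self.tumor.index.equals(self.normal.index):
            raise ValueError("tumor and normal tables list different metabolites")
        if (self.tumor.to_numpy() <= 0).any() or (self.normal.to_numpy() <= 0).any():
            raise ValueError("intensities must be positive")


@dataclass
class PathwayDAResult:
    pathway: str
    n_up: int
    n_down: int
    n_measured: int

    @property
    def da_score(self) -> float:
        return (self.n_up - self.n_down) / self.n_measured


@dataclass
class FluxMatrices:
    """Reaction fluxes R (cell types x reactions) and signed
    stoichiometry S (reactions x metabolites, products +, substrates -)."""

    reaction_flux: pd.DataFrame
    stoichiometry: pd.DataFrame

    def __post_init__(self) -> None:
        for name in self.stoichiometry.columns:
            tag = str(name)[-3:]
            if tag.startswith("[") and tag not in COMPARTMENTS:
                raise ValueError(
                    f"unknown compartment tag in {name!r}; expected one of {COMPARTMENTS}"
                )


def _exact_sf_cdf(ranks2: np.ndarray, w2: int) -> tuple[float, float]:
    """P(W >= w) and P(W <= w) for the signed-rank sum under random signs.

    ranks2 are the doubled ranks (integers even with average-rank ties);
    w2 the doubled observed positive-rank sum.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        counts[r:] += counts[: total + 1 - r]
    denom = counts.sum()  # 2^n
    sf = counts[w2:].sum() / denom
    cdf = counts[: w2 + 1].sum() / denom
    return sf, cdf


def paired_wilcoxon(x, y) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test.

    Returns (W+, p). Zero differences are dropped; |differences| get
    average ranks. Exact enumeration for n <= 25 non-zero pairs, normal
    approximation with continuity and tie correction above.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors differ in length")
    d = x - y
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return 0.0, 1.0
    if n < 3:
        raise ValueError(f"need >=3 non-zero paired differences, got {n}")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= EXACT_N_MAX:
        ranks2 = np.rint(2 * ranks).astype(int)
        w2 = int(round(2 * w_plus))
        sf, cdf = _exact_sf_cdf(ranks2, w2)
        p = min(1.0, 2.0 * min(sf, cdf))
        return w_plus, p

    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return w_plus, p


def differential_metabolites(
    table: PairedMetaboliteTable,
    *,
    alpha: float = 0.05,
    use_adjusted: bool = False,
) -> tuple[set[str], set[str], pd.DataFrame]:
    """Classify metabolites as tumor-up / tumor-down by paired Wilcoxon.

    Direction comes from the median per-pair log2(tumor/normal). Calls
    use the raw p by default (``use_adjusted=True`` gates on BH q
    instead); both are reported.
    """
    t = table.tumor.to_numpy(dtype=float)
    m = table.normal.to_numpy(dtype=float)
    stats, pvals = [], []
    for i in range(t.shape[0]):
        w, p = paired_wilcoxon(t[i], m[i])
        stats.append(w)
        pvals.append(p)
    pvals = np.asarray(pvals)
    qvals = benjamini_hochberg(pvals)
    log2fc = np.median(np.log2(t / m), axis=1)
    crit = qvals if use_adjusted else pvals
    res = pd.DataFrame(
        {
            "W": stats,
            "p_value": pvals,
            "q_value": qvals,
            "log2fc": log2fc,
            "direction": np.where(
                (crit < alpha) & (log2fc > 0),
                "up",
                np.where((crit < alpha) & (log2fc < 0), "down", "ns"),
            ),
        },
        index=table.tumor.index,
    )
    up = set(res.index[res["direction"] == "up"])
    down = set(res.index[res["direction"] == "down"])
    return up, down, res


def da_score(
    up: set[str],
    down: set[str],
    pathways: dict[str, list[str]],
    measured: set[str],
    *,
    min_measured: int = 3,
) -> list[PathwayDAResult]:
    """Differential-abundance score per pathway.

    Counts are restricted to the pathway members actually measured;
    pathways with fewer than ``min_measured`` measured members are
    skipped with a log message.
    """
    if not pathways:
        raise ValueError("empty pathway map")
    if not (up <= measured and down <= measured):
        raise ValueError("up/down sets contain unmeasured metabolites")
    results = []
    n_dropped_members = 0
    for pw, members in pathways.items():
        mset = set(members)
        meas = mset & measured
        n_dropped_members += len(mset - measured)
        if len(meas) < min_measured:
            logger.info(
                "pathway %s skipped: %d measured members (< %d)",
                pw, len(meas), min_measured,
            )
            continue
        results.append(
            PathwayDAResult(
                pathway=pw,
                n_up=len(meas & up),
                n_down=len(meas & down),
                n_measured=len(meas),
            )
        )
    if n_dropped_members:
        logger.info("%d pathway members were not measured", n_dropped_members)
    return results


def da_table(results: list[PathwayDAResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pathway": [r.pathway for r in results],
            "n_up": [r.n_up for r in results],
            "n_down": [r.n_down for r in results],
            "n_measured": [r.n_measured for r in results],
            "da_score": [r.da_score for r in results],
        }
    ).set_index("pathway")


def metabolite_flux(flux: FluxMatrices) -> pd.DataFrame:
    """Cell-type x metabolite flux: product of reaction fluxes and signed
    stoichiometry. Positive = accumulation, negative = consumption."""
    r, s = flux.reaction_flux, flux.stoichiometry
    if not r.columns.equals(s.index):
        if set(r.columns) == set(s.index):
            s = s.loc[r.columns]
        else:
            raise ValueError(
                f"reaction axes differ: flux is {r.shape} over "
                f"{list(r.columns[:3])}..., stoichiometry is {s.shape} over "
                f"{list(s.index[:3])}..."
            )
    return r @ s


def zscore_flux(m: pd.DataFrame, *, ddof: int = 1) -> pd.DataFrame:
    """z-score each metabolite column across cell types (sample SD).

    Zero-variance columns become 0 with a warning.
    """
    if m.shape[0] < 2:
        raise ValueError("z-scoring needs at least 2 cell types")
    sd = m.std(ddof=ddof)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} constant metabolite columns set to z=0")
    sd = sd.replace(0.0, np.inf)
    return (m - m.mean()) / sd
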