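"""Test-quality metrics for paired-cell asymmetry assays.

Two in-situ immunofluorescence assays score whether a biomarker pair is
expressed asymmetrically between sister cells: the sister-pair (SPr) assay
scores adjacent daughter cells after sparse plating, and the cytochalasin-D
(CD) assay scores the two sister nuclei trapped in one undivided cell.  Each
biomarker combination is evaluated under culture conditions promoting
asymmetric (ASYM) vs symmetric (SYM) self-renewal, giving a 2x2 table of
asymmetric-pattern calls.  Under the simplifying condition model — the
engineered lines self-renew 0% asymmetrically under SYM conditions and 100%
under ASYM conditions — every asymmetric-pattern call under ASYM conditions
is a true positive and every one under SYM conditions a false positive,
which turns the table into a diagnostic-test confusion matrix.

Published tables report rounded percentages; :func:`counts_from_percent`
reconstructs the underlying integer counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd
from scipy.stats import fisher_exact as _scipy_fisher

from .data_model import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PairCountTable:
    """Counts of sister pairs (or sister-nuclei pairs) scored asymmetric."""

    n_asym: int      # pairs evaluated under ASYM-promoting conditions
    n_sym: int       # pairs evaluated under SYM-promoting conditions
    k_asym: int      # of those, scored asymmetric under ASYM conditions
    k_sym: int       # scored asymmetric under SYM conditions
    biomarker: str = ""
    assay: str = ""  # "SPr" or "CD"

    def __post_init__(self) -> None:
        if self.n_asym <= 0 or self.n_sym <= 0:
            raise ValidationError("pair counts must be positive")
        if not (0 <= self.k_asym <= self.n_asym and 0 <= self.k_sym <= self.n_sym):
            raise ValidationError("asymmetric-scored counts must lie in [0, n]")


@dataclass
class AssayMetrics:
    """Sensitivity / specificity / PPV (integer percent) and Fisher p."""

    sensitivity: int
    specificity: int
    ppv: int | None          # None when no positive calls were made at all
    fisher_p: float
    table: PairCountTable


@dataclass
class KineticsRecord:
    """Population-division-cycle bookkeeping for one culture."""

    n0: float
    nt: float
    pdc_sym: float    # log2(nt/n0): cycles under exponential (symmetric) growth
    pdc_asym: float   # nt/n0 - 1: cycles under linear (asymmetric) growth
    label: str = ""


def round_half_away(x: float) -> int:
    """Round halves away from zero (the convention of printed percentages)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def counts_from_percent(pct: int, n: int, strict: bool = True) -> int:
    """Reconstruct the integer count behind a rounded percentage.

    Returns the ``k`` with ``round(100k/n) == pct`` closest to ``pct`` in
    exact percent; if two such ``k`` are equally close the smaller is
    returned (logged).  With ``strict=True`` (default) an unreachable
    percentage raises; ``strict=False`` falls back to the globally nearest
    ``k`` (logged), tolerating tables whose printed percent was rounded
    differently.
    """
    if not 0 <= pct <= 100:
        raise ValidationError("percentage out of [0, 100]")
    if n < 1:
        raise ValidationError("pair count must be >= 1")
    candidates = [k for k in range(n + 1) if round_half_away(100 * k / n) == pct]
    if not candidates:
        if strict:
            raise ValidationError(
                f"no count of {n} pairs rounds to {pct}%; the printed value "
                "cannot be reconstructed exactly"
            )
        k = min(range(n + 1), key=lambda k: (abs(100 * k / n - pct), k))
        logger.warning(
            "%d%% of %d pairs is unreachable by rounding; using nearest k=%d (%.2f%%)",
            pct, n, k, 100 * k / n,
        )
        return k
    best = min(abs(100 * k / n - pct) for k in candidates)
    ties = [k for k in candidates if math.isclose(abs(100 * k / n - pct), best)]
    if len(ties) > 1:
        logger.info("percent reconstruction tie for %d%% of %d: %s; using %d", pct, n, ties, ties[0])
    return ties[0]


def fisher_exact(t: PairCountTable) -> float:
    """Two-tailed Fisher's exact test of asymmetric-pattern detection.

    The two-sided p sums the hypergeometric probabilities of every 2x2 table
    with the observed margins whose probability does not exceed the observed
    table's (the probability-mass criterion).
    """
    table = [
        [t.k_asym, t.n_asym - t.k_asym],
        [t.k_sym, t.n_sym - t.k_sym],
    ]
    _, p = _scipy_fisher(table, alternative="two-sided")
    return float(p)


def test_metrics(t: PairCountTable) -> AssayMetrics:
    """Diagnostic-test metrics under the 0%/100% condition model.

    TP = pairs scored asymmetric under ASYM conditions, FN = the remaining
    ASYM-condition pairs, FP = pairs scored asymmetric under SYM conditions,
    TN = the remaining SYM-condition pairs.  Percentages are rounded
    half-away-from-zero for reporting; PPV is None when no positive call was
    made under either condition.
    """
    tp = t.k_asym
    fn = t.n_asym - t.k_asym
    fp = t.k_sym
    tn = t.n_sym - t.k_sym
    sensitivity = round_half_away(100 * tp / (tp + fn))
    specificity = round_half_away(100 * tn / (tn + fp))
    ppv = round_half_away(100 * tp / (tp + fp)) if (tp + fp) > 0 else None
    return AssayMetrics(
        sensitivity=sensitivity,
        specificity=specificity,
        ppv=ppv,
        fisher_p=fisher_exact(t),
        table=t,
    )


def pdc(n0: float, nt: float, expected_cycles: float = 2.0) -> KineticsRecord:
    """Population division cycles under the two growth models.

    Symmetric self-renewal doubles the cycling population every cycle,
    ``pdc_sym = log2(nt/n0)``; pure asymmetric self-renewal keeps one cycling
    cell per lineage, adding one (arrested) cell per cycle,
    ``pdc_asym = nt/n0 - 1``.  The culture is labeled with whichever model's
    cycle count is nearer ``expected_cycles`` (the experiment's known culture
    duration in division cycles); ties label SYM-consistent.
    """
    if n0 <= 0 or nt <= 0:
        raise ValidationError("cell counts must be positive")
    ratio = nt / n0
    pdc_sym = math.log2(ratio)
    pdc_asym = ratio - 1.0
    label = (
        "SYM-consistent"
        if abs(pdc_sym - expected_cycles) <= abs(pdc_asym - expected_cycles)
        else "ASYM-consistent"
    )
    return KineticsRecord(n0=n0, nt=nt, pdc_sym=pdc_sym, pdc_asym=pdc_asym, label=label)


#: Published validation measurements for the three biomarker pairings
#: (assay, % asymmetric pattern under ASYM and SYM conditions, pairs evaluated
#: under each condition).  Percentages are the printed rounded values; counts
#: are reconstructed with :func:`counts_from_percent`.
VALIDATION_ASSAYS = [
    {"biomarker": "CyA:CyD1", "assay": "SPr", "pct_asym": 25, "pct_sym": 3, "n_asym": 61, "n_sym": 60},
    {"biomarker": "CyA:CyD1", "assay": "CD", "pct_asym": 25, "pct_sym": 2, "n_asym": 63, "n_sym": 60},
    {"biomarker": "CyA:Btg2", "assay": "SPr", "pct_asym": 47, "pct_sym": 6, "n_asym": 60, "n_sym": 50},
    {"biomarker": "CyA:Btg2", "assay": "CD", "pct_asym": 43, "pct_sym": 5, "n_asym": 53, "n_sym": 61},
    {"biomarker": "CyA:H2A.Z", "assay": "SPr", "pct_asym": 43, "pct_sym": 5, "n_asym": 58, "n_sym": 57},
    {"biomarker": "CyA:H2A.Z", "assay": "CD", "pct_asym": 37, "pct_sym": 3, "n_asym": 63, "n_sym": 59},
]


def table_from_percents(
    biomarker: str,
    assay: str,
    pct_asym: int,
    pct_sym: int,
    n_asym: int,
    n_sym: int,
    strict: bool = True,
) -> PairCountTable:
    """Build a :class:`PairCountTable` from printed rounded percentages."""
    return PairCountTable(
        n_asym=n_asym,
        n_sym=n_sym,
        k_asym=counts_from_percent(pct_asym, n_asym, strict=strict),
        k_sym=counts_from_percent(pct_sym, n_sym, strict=strict),
        biomarker=biomarker,
        assay=assay,
    )


def metrics_frame(rows=None, strict: bool = True) -> pd.DataFrame:
    """Metrics table for a list of percent-style rows (default: the published
    validation assays)."""
    rows = VALIDATION_ASSAYS if rows is None else rows
    out = []
    for r in rows:
        t = table_from_percents(strict=strict, **r)
        m = test_metrics(t)
        out.append(
            {
                "biomarker": t.biomarker,
                "assay": t.assay,
                "k_asym": t.k_asym,
                "n_asym": t.n_asym,
                "k_sym": t.k_sym,
                "n_sym": t.n_sym,
                "fisher_p": m.fisher_p,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "ppv": m.ppv,
            }
        )
    return pd.DataFrame(out)


def read_counts_tsv(path, strict: bool = True) -> list[PairCountTable]:
    """Read a pair-count TSV (columns: biomarker, assay, then either
    k_asym/k_sym or pct_asym/pct_sym, plus n_asym, n_sym)."""
    df = pd.read_csv(path, sep="\t")
    tables = []
    for _, row in df.iterrows():
        if "k_asym" in df.columns and not pd.isna(row.get("k_asym")):
            k_asym, k_sym = int(row["k_asym"]), int(row["k_sym"])
        else:
            k_asym = counts_from_percent(int(row["pct_asym"]), int(row["n_asym"]), strict=strict)
            k_sym = counts_from_percent(int(row["pct_sym"]), int(row["n_sym"]), strict=strict)
        tables.append(
            PairCountTable(
                n_asym=int(row["n_asym"]),
                n_sym=int(row["n_sym"]),
                k_asym=k_asym,
                k_sym=k_sym,
                biomarker=str(row.get("biomarker", "")),
                assay=str(row.get("assay", "")),
            )
        )
    return tables
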