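"""Three-state intersection classifier for self-renewal-pattern categories.

Two rank-products comparisons are combined: A = ASYM vs SYM and
B = ASYM vs p53SYM.  Genes significant in both comparisons with a consistent
direction form the ASRA signature (ASRA_up / ASRA_down); genes significant in
exactly one comparison, or in both with opposite directions, fall into the six
remaining self-renewal-pattern-associated (SRPA) categories.  Up-regulated
ASRA genes whose detection call is "A" (absent) on every SYM-state array are
additionally flagged "exclusive" — candidates for biomarkers expressed only
during asymmetric self-renewal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import ExpressionMatrix, ValidationError
from .rankprod import DifferentialResult

ASRA_CATEGORIES = ("ASRA_up", "ASRA_down")
SRPA_CATEGORIES = ("A_up", "A_down", "B_up", "B_down", "A_up/B_down", "A_down/B_up")
ALL_CATEGORIES = ASRA_CATEGORIES + SRPA_CATEGORIES + ("none",)


def classify_gene(
    sig_a_up: bool, sig_a_down: bool, sig_b_up: bool, sig_b_down: bool
) -> str:
    """Category from the four per-comparison significance flags."""
    if (sig_a_up and sig_a_down) or (sig_b_up and sig_b_down):
        raise ValidationError("a gene cannot be significant in both directions of one comparison")
    if sig_a_up and sig_b_up:
        return "ASRA_up"
    if sig_a_down and sig_b_down:
        return "ASRA_down"
    if sig_a_up and sig_b_down:
        return "A_up/B_down"
    if sig_a_down and sig_b_up:
        return "A_down/B_up"
    if sig_a_up:
        return "A_up"
    if sig_a_down:
        return "A_down"
    if sig_b_up:
        return "B_up"
    if sig_b_down:
        return "B_down"
    return "none"


def exclusive_flag(
    calls: pd.Series, sym_samples, p53sym_samples
) -> tuple[bool, bool]:
    """Absence flags for one gene from its detection calls.

    Returns ``(absent_in_sym_state, absent_in_any_sym_state)``:
    the first is true iff every SYM-condition array calls "A"; the second iff
    every array of at least one of the two symmetric states (SYM, p53SYM)
    calls "A".  Marginal ("M") calls never count as absent.
    """
    for s in list(sym_samples) + list(p53sym_samples):
        if s not in calls.index or pd.isna(calls[s]):
            raise ValidationError(f"missing detection call for sample {s!r}")
    absent_sym = bool(all(calls[s] == "A" for s in sym_samples))
    absent_p53 = bool(all(calls[s] == "A" for s in p53sym_samples))
    return absent_sym, absent_sym or absent_p53


@dataclass
class SignatureTable:
    """Per-gene category table plus expression/call summaries.

    ``table`` columns: category, exclusive, absent_sym, absent_p53sym,
    absent_in_any, fc_A, fc_B, mean_ASYM, mean_SYM, mean_p53SYM,
    calls_ASYM, calls_SYM, calls_p53SYM.  Absence columns are nullable
    booleans; they are left missing when the matrix carries no detection
    calls.
    """

    table: pd.DataFrame
    cutoff: float

    @property
    def categories(self) -> pd.Series:
        return self.table["category"]

    def genes_in(self, *categories: str) -> list[str]:
        return list(self.table.index[self.table["category"].isin(categories)])

    @property
    def asra_genes(self) -> list[str]:
        return self.genes_in(*ASRA_CATEGORIES)

    def signature_frame(self) -> pd.DataFrame:
        """Rows with a non-'none' category (the exported signature table)."""
        return self.table[self.table["category"] != "none"]

    def write_tsv(self, path, include_none: bool = False) -> None:
        df = self.table if include_none else self.signature_frame()
        df.to_csv(path, sep="\t", float_format="%.6f")


def _call_summary(calls: pd.DataFrame, samples) -> pd.Series:
    """Per-state detection-call summary: single char if unanimous,
    else '!' followed by the individual replicate calls."""
    sub = calls[samples]
    first = sub.iloc[:, 0]
    unanimous = sub.eq(first, axis=0).all(axis=1)
    joined = sub.apply(lambda row: "!" + "".join(row), axis=1)
    return first.where(unanimous, joined)


def build_signature(
    diff_a: DifferentialResult,
    diff_b: DifferentialResult,
    x: ExpressionMatrix,
    asym_label: str = "ASYM",
    sym_label: str = "SYM",
    p53sym_label: str = "p53SYM",
) -> SignatureTable:
    """Combine the A and B comparisons into the category table.

    ``diff_a``/``diff_b`` must be computed on the same gene universe as ``x``.
    When ``x`` lacks detection calls the exclusive/absence columns are left
    missing (NA) rather than failing.
    """
    if list(diff_a.gene_ids) != list(diff_b.gene_ids) or list(diff_a.gene_ids) != x.gene_ids:
        raise ValidationError("A/B comparisons and expression matrix must share one gene universe")

    a_up = np.asarray(diff_a.sig_up, dtype=bool)
    a_down = np.asarray(diff_a.sig_down, dtype=bool)
    b_up = np.asarray(diff_b.sig_up, dtype=bool)
    b_down = np.asarray(diff_b.sig_down, dtype=bool)
    if (a_up & a_down).any() or (b_up & b_down).any():
        raise ValidationError("contradictory significance flags")

    category = np.full(x.n_genes, "none", dtype=object)
    category[a_up & b_up] = "ASRA_up"
    category[a_down & b_down] = "ASRA_down"
    category[a_up & b_down] = "A_up/B_down"
    category[a_down & b_up] = "A_down/B_up"
    category[a_up & ~b_up & ~b_down] = "A_up"
    category[a_down & ~b_up & ~b_down] = "A_down"
    category[b_up & ~a_up & ~a_down] = "B_up"
    category[b_down & ~a_up & ~a_down] = "B_down"

    asym = x.samples_of(asym_label)
    sym = x.samples_of(sym_label)
    p53 = x.samples_of(p53sym_label)

    table = pd.DataFrame(index=pd.Index(x.gene_ids, name="gene_id"))
    table["category"] = category
    if x.calls is not None:
        absent_sym = x.calls[sym].eq("A").all(axis=1)
        absent_p53 = x.calls[p53].eq("A").all(axis=1)
        table["exclusive"] = (category == "ASRA_up") & absent_sym
        table["absent_sym"] = absent_sym
        table["absent_p53sym"] = absent_p53
        table["absent_in_any"] = absent_sym | absent_p53
    else:
        table["exclusive"] = pd.array([pd.NA] * x.n_genes, dtype="boolean")
        table["absent_sym"] = pd.array([pd.NA] * x.n_genes, dtype="boolean")
        table["absent_p53sym"] = pd.array([pd.NA] * x.n_genes, dtype="boolean")
        table["absent_in_any"] = pd.array([pd.NA] * x.n_genes, dtype="boolean")
    table["fc_A"] = diff_a.fc
    table["fc_B"] = diff_b.fc
    table["mean_ASYM"] = x.values[asym].mean(axis=1)
    table["mean_SYM"] = x.values[sym].mean(axis=1)
    table["mean_p53SYM"] = x.values[p53].mean(axis=1)
    if x.calls is not None:
        table["calls_ASYM"] = _call_summary(x.calls, asym)
        table["calls_SYM"] = _call_summary(x.calls, sym)
        table["calls_p53SYM"] = _call_summary(x.calls, p53)
    return SignatureTable(table=table, cutoff=diff_a.cutoff)


def summarize(t: SignatureTable) -> dict:
    """Category counts plus signature-level totals.

    ``SRPA`` is the total of the six non-ASRA categories; ``exclusive`` and
    ``absent_in_any`` count up-regulated ASRA genes with the respective
    absence property (None when detection calls were unavailable).
    """
    counts = t.table["category"].value_counts()
    out = {cat: int(counts.get(cat, 0)) for cat in ALL_CATEGORIES}
    out["ASRA"] = out["ASRA_up"] + out["ASRA_down"]
    out["SRPA"] = sum(out[c] for c in SRPA_CATEGORIES)
    if t.table["exclusive"].isna().any():
        out["exclusive"] = None
        out["absent_in_any"] = None
    else:
        out["exclusive"] = int(t.table["exclusive"].sum())
        up = t.table["category"] == "ASRA_up"
        out["absent_in_any"] = int(t.table.loc[up, "absent_in_any"].sum())
    out["total_genes"] = int(len(t.table))
    return out
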