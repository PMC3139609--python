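"""Synthetic microarray generator with planted self-renewal-pattern structure.

Emulates the statistical structure of the discovery experiment: an 8-array
training design (3 ASYM, 3 SYM, 2 p53SYM arrays over 22,587 genes) in which
known numbers of genes are planted into each self-renewal-pattern category
(ASRA_up/down, A_up/down, B_up/down and the two mixed categories), including
genes whose expression is undetectable ("absent" detection call) in one or
both symmetric states.  Every planted gene's per-state true mean realizes its
category's semantics; observed log2 values are true mean + Gaussian noise;
detection calls derive from a threshold on the observed value.

The generator is the test bed for the whole pipeline: the planted truth table
is the reference every recovery test compares against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .data_model import ExpressionMatrix, ValidationError

#: categories a gene can be planted into ("none" = not differentially expressed)
CATEGORIES = (
    "ASRA_up",
    "ASRA_down",
    "A_up",
    "A_down",
    "B_up",
    "B_down",
    "A_up/B_down",
    "A_down/B_up",
    "none",
)

STATES = ("ASYM", "SYM", "p53SYM")


@dataclass
class PlantConfig:
    """Composition and noise model of the planted training design.

    Category sizes default to the published signature composition
    (85 ASRA genes of which 7 down-regulated; 11 "exclusive" up-regulated
    genes absent on every SYM array; 20 absent in at least one symmetric
    state; 320/265/194/56/5/5 genes in the six single- or mixed-comparison
    categories, totalling 845).  Planted log2 shifts default to 2.0
    (4-fold); the up-regulated ASRA genes span 2.0..4.52 (4- to 23-fold),
    the published induction range of the most-induced genes.
    """

    n_genes: int = 22587
    n_asym: int = 3
    n_sym: int = 3
    n_p53sym: int = 2
    n_asra_up: int = 78
    n_asra_down: int = 7
    n_exclusive: int = 11          # absent on all SYM arrays; subset of ASRA_up
    n_absent_any: int = 20         # absent in >=1 symmetric state; subset of ASRA_up
    n_a_up: int = 320
    n_a_down: int = 265
    n_b_up: int = 194
    n_b_down: int = 56
    n_a_up_b_down: int = 5
    n_a_down_b_up: int = 5
    baseline_mean: float = 8.0     # log2 units
    baseline_sd: float = 1.5
    effect_min: float = 2.0        # log2 shift of planted genes (4-fold)
    effect_max: float = 4.52       # upper end for ASRA_up genes (~23-fold)
    noise_sd: float = 0.15         # per-array Gaussian log2 noise
    tau: float = 5.0               # detection threshold: value < tau -> "A"
    marginal_band: float = 0.5     # tau <= value < tau+band -> "M"
    absent_mean: float = 4.0       # true mean of states planted as undetectable
    call_margin: float = 0.6       # keeps detectable means clear of the M band
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < self.n_planted:
            raise ValidationError("category sizes exceed n_genes")
        if not (self.n_exclusive <= self.n_absent_any <= self.n_asra_up):
            raise ValidationError("need exclusive <= absent-in-any <= ASRA_up")
        if self.effect_min <= 0 or self.effect_max < self.effect_min:
            raise ValidationError("effect range must be positive")
        if min(self.n_asym, self.n_sym, self.n_p53sym) < 1:
            raise ValidationError("each state needs at least one replicate")
        if self.noise_sd < 0 or self.baseline_sd <= 0:
            raise ValidationError("noise/baseline sd out of range")
        if self.absent_mean >= self.tau:
            raise ValidationError("absent_mean must sit below the detection threshold")

    @property
    def n_planted(self) -> int:
        return (
            self.n_asra_up + self.n_asra_down + self.n_a_up + self.n_a_down
            + self.n_b_up + self.n_b_down + self.n_a_up_b_down + self.n_a_down_b_up
        )

    @property
    def sample_ids(self) -> list[str]:
        return (
            [f"ASYM_{i+1}" for i in range(self.n_asym)]
            + [f"SYM_{i+1}" for i in range(self.n_sym)]
            + [f"p53SYM_{i+1}" for i in range(self.n_p53sym)]
        )

    @property
    def conditions(self) -> pd.Series:
        labels = (
            ["ASYM"] * self.n_asym + ["SYM"] * self.n_sym + ["p53SYM"] * self.n_p53sym
        )
        return pd.Series(labels, index=self.sample_ids)

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"g{i+1:0{width}d}" for i in range(self.n_genes)]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthTable:
    """Planted per-gene ground truth: category, absence flags, per-state means."""

    table: pd.DataFrame  # columns: category, exclusive, absent_sym, absent_p53sym,
    #                                mean_ASYM, mean_SYM, mean_p53SYM
    config: PlantConfig

    @property
    def categories(self) -> pd.Series:
        return self.table["category"]

    def genes_in(self, category: str) -> list[str]:
        return list(self.table.index[self.table["category"] == category])

    @property
    def asra_genes(self) -> list[str]:
        return list(
            self.table.index[self.table["category"].isin(["ASRA_up", "ASRA_down"])]
        )

    def counts(self) -> dict:
        c = self.table["category"].value_counts()
        out = {cat: int(c.get(cat, 0)) for cat in CATEGORIES}
        out["ASRA"] = out["ASRA_up"] + out["ASRA_down"]
        out["SRPA"] = sum(
            out[k] for k in ("A_up", "A_down", "B_up", "B_down", "A_up/B_down", "A_down/B_up")
        )
        out["exclusive"] = int(self.table["exclusive"].sum())
        up = self.table["category"] == "ASRA_up"
        out["absent_in_any"] = int(
            (self.table.loc[up, "absent_sym"] | self.table.loc[up, "absent_p53sym"]).sum()
        )
        return out


def _truncated_normal(rng, mean, sd, lower, size):
    """Normal(mean, sd) conditioned on >= lower, via inverse-CDF sampling."""
    lower = np.broadcast_to(np.asarray(lower, dtype=float), (size,))
    a = ndtr((lower - mean) / sd)  # CDF at the truncation point
    u = rng.uniform(a, 1.0, size=size)
    return mean + sd * ndtri(u)


def truth_table(cfg: PlantConfig, seed: int | None = None) -> TruthTable:
    """Deterministic planted layout for a config (and seed).

    Category positions are shuffled over the gene universe; per-state true
    means are built as baseline + nonnegative per-state shifts so that no
    detectable state ever drifts into the absent/marginal call band.
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    genes = cfg.gene_ids()
    G = cfg.n_genes

    order = rng.permutation(G)
    blocks = [
        ("ASRA_up", cfg.n_asra_up),
        ("ASRA_down", cfg.n_asra_down),
        ("A_up", cfg.n_a_up),
        ("A_down", cfg.n_a_down),
        ("B_up", cfg.n_b_up),
        ("B_down", cfg.n_b_down),
        ("A_up/B_down", cfg.n_a_up_b_down),
        ("A_down/B_up", cfg.n_a_down_b_up),
    ]
    category = np.full(G, "none", dtype=object)
    idx_of: dict[str, np.ndarray] = {}
    pos = 0
    for name, size in blocks:
        idx = order[pos : pos + size]
        category[idx] = name
        idx_of[name] = idx
        pos += size

    # nonnegative per-state shifts realizing each category's semantics;
    # "~" pairs (e.g. p53SYM ~ ASYM for A-only genes) are equal true means.
    delta = cfg.effect_min
    shift = {s: np.zeros(G) for s in STATES}
    asra_up = idx_of["ASRA_up"]
    up_effects = np.linspace(cfg.effect_min, cfg.effect_max, max(len(asra_up), 1))
    shift["ASYM"][asra_up] = up_effects[: len(asra_up)]
    shift["ASYM"][idx_of["ASRA_down"]] = 0.0
    shift["SYM"][idx_of["ASRA_down"]] = delta
    shift["p53SYM"][idx_of["ASRA_down"]] = delta
    # A_up: up vs SYM only; p53SYM tracks ASYM
    shift["ASYM"][idx_of["A_up"]] = delta
    shift["p53SYM"][idx_of["A_up"]] = delta
    # A_down: down vs SYM only; p53SYM tracks ASYM
    shift["SYM"][idx_of["A_down"]] = delta
    # B_up: up vs p53SYM only; SYM tracks ASYM
    shift["ASYM"][idx_of["B_up"]] = delta
    shift["SYM"][idx_of["B_up"]] = delta
    # B_down: down vs p53SYM only; SYM tracks ASYM
    shift["p53SYM"][idx_of["B_down"]] = delta
    # mixed categories: SYM < ASYM < p53SYM and p53SYM < ASYM < SYM
    shift["ASYM"][idx_of["A_up/B_down"]] = delta
    shift["p53SYM"][idx_of["A_up/B_down"]] = 2 * delta
    shift["SYM"][idx_of["A_down/B_up"]] = 2 * delta
    shift["ASYM"][idx_of["A_down/B_up"]] = delta

    floor = cfg.tau + cfg.marginal_band + cfg.call_margin
    baseline = _truncated_normal(rng, cfg.baseline_mean, cfg.baseline_sd, floor, G)

    means = {s: baseline + shift[s] for s in STATES}

    # absence structure: the first n_exclusive ASRA_up genes are undetectable in
    # the SYM state (and, sharing the low mean, in p53SYM); the next
    # (n_absent_any - n_exclusive) are undetectable in p53SYM only.
    absent_sym = np.zeros(G, dtype=bool)
    absent_p53 = np.zeros(G, dtype=bool)
    excl = asra_up[: cfg.n_exclusive]
    p53_only = asra_up[cfg.n_exclusive : cfg.n_absent_any]
    absent_sym[excl] = True
    absent_p53[excl] = True
    absent_p53[p53_only] = True
    means["SYM"] = np.where(absent_sym, cfg.absent_mean, means["SYM"])
    means["p53SYM"] = np.where(absent_p53, cfg.absent_mean, means["p53SYM"])
    # up-shift is applied to the detectable background, keeping ASRA_up genes
    # clearly induced over both symmetric states
    means["ASYM"][excl] = cfg.absent_mean + cfg.call_margin + cfg.marginal_band + shift[
        "ASYM"
    ][excl]

    table = pd.DataFrame(
        {
            "category": category,
            "exclusive": (category == "ASRA_up") & absent_sym,
            "absent_sym": absent_sym,
            "absent_p53sym": absent_p53,
            "mean_ASYM": means["ASYM"],
            "mean_SYM": means["SYM"],
            "mean_p53SYM": means["p53SYM"],
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return TruthTable(table=table, config=cfg)


def _calls_from_values(values: np.ndarray, tau: float, band: float) -> np.ndarray:
    calls = np.full(values.shape, "P", dtype=object)
    calls[values < tau + band] = "M"
    calls[values < tau] = "A"
    return calls


def generate_training(
    cfg: PlantConfig | None = None, seed: int | None = None
) -> tuple[ExpressionMatrix, TruthTable]:
    """Generate the planted 8-array training design.

    Returns the expression matrix (with detection calls and condition labels
    attached) and the planted truth table.  Reproducible for a fixed seed.
    """
    cfg = cfg or PlantConfig()
    seed = cfg.seed if seed is None else seed
    truth = truth_table(cfg, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))

    mean_cols = {s: truth.table[f"mean_{s}"].to_numpy() for s in STATES}
    columns = {}
    for sample, state in cfg.conditions.items():
        noise = rng.normal(0.0, cfg.noise_sd, cfg.n_genes) if cfg.noise_sd > 0 else 0.0
        columns[sample] = mean_cols[state] + noise
    values = pd.DataFrame(columns, index=truth.table.index)
    calls = pd.DataFrame(
        _calls_from_values(values.to_numpy(), cfg.tau, cfg.marginal_band),
        index=values.index,
        columns=values.columns,
    )
    x = ExpressionMatrix(values=values, calls=calls, conditions=cfg.conditions)
    return x, truth


def generate_testset(
    profile: str,
    cfg: PlantConfig | None = None,
    seed: int = 0,
    n_samples: int = 3,
    dropout: float = 0.0,
    custom_offsets: dict | None = None,
    truth: TruthTable | None = None,
) -> ExpressionMatrix:
    """Generate an external-style test set sharing the planted gene universe.

    ``profile`` selects the expression program over planted genes:

    * ``"NSC-like"`` — samples carry the ASYM-state profile (the pattern of a
      tissue stem cell population with asymmetric self-renewal character);
    * ``"ESC-like"`` — samples carry the SYM-state profile (symmetric,
      embryonic-stem-cell-like character);
    * ``"custom"`` — SYM-state baseline plus ``custom_offsets`` (log2 shift
      per category).

    ``dropout`` removes a random fraction of genes, simulating platform
    mismatch with the training universe.
    """
    cfg = cfg or PlantConfig()
    if not 0.0 <= dropout < 1.0:
        raise ValidationError("dropout must be in [0, 1)")
    if truth is None:
        truth = truth_table(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))

    if profile == "NSC-like":
        base = truth.table["mean_ASYM"].to_numpy().copy()
    elif profile == "ESC-like":
        base = truth.table["mean_SYM"].to_numpy().copy()
    elif profile == "custom":
        base = truth.table["mean_SYM"].to_numpy().copy()
        for cat, off in (custom_offsets or {}).items():
            if cat not in CATEGORIES:
                raise ValidationError(f"unknown category {cat!r} in custom offsets")
            base[truth.table["category"].to_numpy() == cat] += off
    else:
        raise ValidationError(
            f"unknown profile {profile!r}; expected NSC-like, ESC-like or custom"
        )

    tag = profile.replace("-like", "")
    columns = {
        f"{tag}_{i+1}": base + rng.normal(0.0, cfg.noise_sd, cfg.n_genes)
        for i in range(n_samples)
    }
    values = pd.DataFrame(columns, index=truth.table.index)
    if dropout > 0:
        keep = rng.random(cfg.n_genes) >= dropout
        values = values.loc[keep]
    conditions = pd.Series(profile, index=values.columns)
    calls = pd.DataFrame(
        _calls_from_values(values.to_numpy(), cfg.tau, cfg.marginal_band),
        index=values.index,
        columns=values.columns,
    )
    return ExpressionMatrix(values=values, calls=calls, conditions=conditions)


def write_truth_tsv(truth: TruthTable, path) -> None:
    truth.table.to_csv(path, sep="\t", float_format="%.6f")
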