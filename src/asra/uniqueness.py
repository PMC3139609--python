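"""Random-subset evaluation of a gene signature's discriminating uniqueness.

How special is a discovered signature, compared to same-sized gene subsets
drawn at random from the analyzed universe?  Each random subset is evaluated
exactly like the signature: fit the two-group BGA discriminator on the
training arrays restricted to the subset, project the training samples, and
take the two-sided pooled-variance Student's t p-value of the group
separation.  The resulting null distribution yields (i) the signature's
percentile, (ii) the over-representation of signature genes among subsets
that discriminate better than the signature (against the hypergeometric
expectation), and (iii) — given two external test sets — the distribution of
each subset's test-set separation relative to its training separation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .bga import bga_fit, project, separation_pvalue, separation_distance
from .data_model import ExpressionMatrix, GeneSet, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class SubsetEvaluation:
    """One random subset's discrimination result."""

    subset: GeneSet
    p: float
    n_signature: int = 0
    rel_separation: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValidationError("p-value out of [0, 1]")
        if not 0 <= self.n_signature <= len(self.subset):
            raise ValidationError("signature overlap exceeds subset size")


@dataclass
class NullDistribution:
    """Evaluations of ``n_draws`` random subsets plus the reference signature."""

    evaluations: list
    n_draws: int
    seed: int
    signature_p: float | None = None
    signature_name: str = ""

    def __post_init__(self) -> None:
        if len(self.evaluations) != self.n_draws:
            raise ValidationError("evaluation count does not match n_draws")

    @property
    def pvalues(self) -> np.ndarray:
        return np.array([e.p for e in self.evaluations])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "p": self.pvalues,
                "n_signature_genes": [e.n_signature for e in self.evaluations],
                "rel_separation": [e.rel_separation for e in self.evaluations],
            },
            index=pd.Index(range(1, self.n_draws + 1), name="draw"),
        )


def sample_subsets(
    universe: GeneSet, size: int, n: int, seed: int = 0
) -> list[GeneSet]:
    """Draw ``n`` subsets of ``size`` genes uniformly without replacement.

    Draws are independent across subsets and reproducible for a fixed seed
    (members are sorted before sampling so the result does not depend on set
    iteration order).
    """
    if size > len(universe):
        raise ValidationError(f"subset size {size} exceeds universe size {len(universe)}")
    if n < 1:
        raise ValidationError("need at least one draw")
    members = np.array(universe.sorted_members())
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        picked = rng.choice(members, size=size, replace=False)
        out.append(GeneSet(name=f"random_{i+1}", members=frozenset(picked.tolist())))
    return out


def _subset_pvalue(
    x: ExpressionMatrix, groups: pd.Series, genes: list, reference: str
) -> float:
    sub = x.subset_genes(genes)
    model = bga_fit(sub, groups=groups, reference=reference)
    coords = project(model, sub)
    a = coords[groups == model.negative_group]
    b = coords[groups == model.positive_group]
    _, p = separation_pvalue(a, b)
    return p


def evaluate_subsets(
    x: ExpressionMatrix,
    groups: pd.Series | dict,
    subsets: list,
    signature: GeneSet | None = None,
    reference: str = "SYM",
    seed: int = 0,
) -> NullDistribution:
    """Discrimination p-value for every subset (and for the signature).

    ``groups`` is the two-level training labeling (canonically ASYM vs the
    merged SYM/p53SYM group).  Subset genes are ordered deterministically
    (sorted) before fitting.
    """
    groups = pd.Series(groups).reindex(x.sample_ids)
    if groups.isna().any():
        raise ValidationError("every training sample needs a group label")
    evaluations = []
    for s in subsets:
        genes = [g for g in s.sorted_members() if g in x.values.index]
        if len(genes) < 2:
            raise ValidationError(f"subset {s.name!r} shares <2 genes with the matrix")
        p = _subset_pvalue(x, groups, genes, reference)
        n_sig = len(s.members & signature.members) if signature is not None else 0
        evaluations.append(SubsetEvaluation(subset=s, p=p, n_signature=n_sig))
    signature_p = None
    sig_name = ""
    if signature is not None:
        genes = [g for g in signature.sorted_members() if g in x.values.index]
        signature_p = _subset_pvalue(x, groups, genes, reference)
        sig_name = signature.name
    return NullDistribution(
        evaluations=evaluations,
        n_draws=len(subsets),
        seed=seed,
        signature_p=signature_p,
        signature_name=sig_name,
    )


def percentile_rank(d: NullDistribution) -> tuple[int, float]:
    """How many random subsets discriminate better than the signature.

    Returns ``(count_better, percentile)`` with strict inequality
    ``p < signature_p`` and ``percentile = 100 * count_better / n_draws``.
    """
    if d.signature_p is None:
        raise ValidationError("distribution carries no signature p-value")
    count_better = int((d.pvalues < d.signature_p).sum())
    return count_better, 100.0 * count_better / d.n_draws


def enrichment_vs_chance(
    d: NullDistribution, signature: GeneSet, universe: GeneSet
) -> pd.DataFrame:
    """Observed vs hypergeometric-expected signature-gene content of the
    better-than-signature subsets.

    Rows are k = 0, 1, 2, ... signature genes per subset; ``observed`` counts
    better subsets containing exactly k, ``expected`` is
    ``count_better * Hypergeom(k; |universe|, |signature|, subset size)``.
    Returns an empty frame (with a warning) when no subset beats the
    signature.
    """
    count_better, _ = percentile_rank(d)
    if count_better == 0:
        logger.warning("no random subset discriminates better than the signature")
        return pd.DataFrame(columns=["k", "observed", "expected"]).set_index("k")
    better = [e for e in d.evaluations if e.p < d.signature_p]
    sizes = {len(e.subset) for e in better}
    if len(sizes) != 1:
        raise ValidationError("subsets must share one size for the enrichment table")
    size = sizes.pop()
    ks = np.array([e.n_signature for e in better])
    k_max = max(int(ks.max()), 0)
    rows = []
    rv = hypergeom(len(universe), len(signature), size)
    for k in range(k_max + 1):
        rows.append(
            {
                "k": k,
                "observed": int((ks == k).sum()),
                "expected": count_better * float(rv.pmf(k)),
            }
        )
    # fold the tail beyond k_max into the last expected bin's complement
    tail = count_better * float(rv.sf(k_max))
    if tail > 1e-9:
        rows.append({"k": k_max + 1, "observed": 0, "expected": tail})
    return pd.DataFrame(rows).set_index("k")


def relative_separation(
    x_train: ExpressionMatrix,
    groups_train: pd.Series | dict,
    test_a: ExpressionMatrix,
    test_b: ExpressionMatrix,
    subsets: list,
    reference: str = "SYM",
) -> tuple[pd.Series, dict]:
    """Per-subset test-set separation relative to the training separation.

    ``test_a`` plays the asymmetric-character role (e.g. neural stem cells),
    ``test_b`` the symmetric one (e.g. embryonic stem cells).  For each
    subset the BGA model is fitted on the training arrays, both test sets are
    projected, and the ratio

        rel = (mean coord of test_b - mean coord of test_a) / training separation

    is recorded; positive rel means the test sets are ordered like the
    training groups.  Subsets with zero training separation are skipped
    (logged).  The summary groups rel <= 0 as "<0" and reports the fraction
    with rel > 1 (greater separation than training).
    """
    groups_train = pd.Series(groups_train).reindex(x_train.sample_ids)
    rels = {}
    for s in subsets:
        genes = [
            g
            for g in s.sorted_members()
            if g in x_train.values.index
            and g in test_a.values.index
            and g in test_b.values.index
        ]
        if len(genes) < 2:
            logger.warning("subset %s shares <2 genes with the test sets; skipped", s.name)
            continue
        sub = x_train.subset_genes(genes)
        model = bga_fit(sub, groups=groups_train, reference=reference)
        if model.degenerate or model.eigenvalue <= 0:
            logger.warning("subset %s: degenerate training model; skipped", s.name)
            continue
        coords_train = project(model, sub)
        train_sep = separation_distance(
            coords_train, groups_train, model.negative_group, model.positive_group
        )
        if train_sep == 0:
            logger.warning("subset %s: zero training separation; skipped", s.name)
            continue
        ca = project(model, test_a.subset_genes(genes))
        cb = project(model, test_b.subset_genes(genes))
        rels[s.name] = float((cb.mean() - ca.mean()) / train_sep)
    rel = pd.Series(rels, name="rel_separation")
    n = len(rel)
    summary = {
        "n_evaluated": n,
        "fraction_gt1": float((rel > 1).sum() / n) if n else float("nan"),
        "fraction_lt0": float((rel <= 0).sum() / n) if n else float("nan"),
    }
    return rel, summary
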