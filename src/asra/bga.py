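"""Correspondence analysis and two-group between-group analysis (BGA).

BGA here is the supervised ordination used to classify self-renewal pattern:
a correspondence analysis (COA) of the genes x group-mean table produces a
single discriminator axis for two groups; independent samples are placed on
the axis by the supplementary-column transition formula, and classified by
which side of the decision boundary (midpoint of the two group centroids,
by default) they fall on.  The orientation convention puts the symmetric
self-renewal group on the positive side, so "symmetric character" is up and
"asymmetric character" is down, mirroring the training classification field.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ExpressionMatrix, GeneSet, ValidationError, match_genes

logger = logging.getLogger(__name__)

SYMMETRIC_LABEL = "symmetric-character"
ASYMMETRIC_LABEL = "asymmetric-character"


class DegenerateModelError(ValidationError):
    """The fitted discriminator axis carries no inertia."""


@dataclass
class Ordination:
    """Correspondence-analysis result.

    Coordinates are principal (scaled by the singular value); ``row_standard``
    additionally carries the standard row coordinates used by the
    supplementary-column transition formula.
    """

    row_coords: np.ndarray      # (I, n_axes)
    col_coords: np.ndarray      # (J, n_axes)
    row_standard: np.ndarray    # (I, n_axes)
    eigenvalues: np.ndarray     # (n_axes,) principal inertias
    row_masses: np.ndarray
    col_masses: np.ndarray
    total_inertia: float
    row_ids: list = field(default_factory=list)
    col_ids: list = field(default_factory=list)

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)


def coa(m, row_ids=None, col_ids=None, tol: float = 1e-12) -> Ordination:
    """Standard correspondence analysis of a nonnegative matrix.

    P = m / total; residual S = D_r^{-1/2} (P - r c^T) D_c^{-1/2}; the
    singular decomposition of S gives the axes.  Axes with singular value
    below ``tol`` (relative to the largest) are dropped; a matrix with no
    association (e.g. proportional columns) yields zero axes and zero
    total inertia.
    """
    if isinstance(m, pd.DataFrame):
        row_ids = list(m.index) if row_ids is None else row_ids
        col_ids = list(m.columns) if col_ids is None else col_ids
        m = m.to_numpy(dtype=float)
    m = np.asarray(m, dtype=float)
    if m.ndim != 2:
        raise ValidationError("input must be a 2-D matrix")
    if (m < 0).any():
        raise ValidationError(
            "correspondence analysis requires nonnegative entries; shift the "
            "matrix (add |min|) before fitting if negative values are expected"
        )
    total = m.sum()
    if total <= 0:
        raise ValidationError("matrix total must be positive")
    P = m / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    if (r <= 0).any() or (c <= 0).any():
        raise ValidationError("zero row or column margin")
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    scale = sv[0] if sv.size and sv[0] > 0 else 1.0
    keep = sv > max(tol * scale, tol)
    U, sv, Vt = U[:, keep], sv[keep], Vt[keep, :]
    row_standard = U / np.sqrt(r)[:, None]
    row_coords = row_standard * sv[None, :]
    col_standard = Vt.T / np.sqrt(c)[:, None]
    col_coords = col_standard * sv[None, :]
    return Ordination(
        row_coords=row_coords,
        col_coords=col_coords,
        row_standard=row_standard,
        eigenvalues=sv**2,
        row_masses=r,
        col_masses=c,
        total_inertia=float((S**2).sum()),
        row_ids=row_ids or [],
        col_ids=col_ids or [],
    )


@dataclass
class BGAModel:
    """Fitted two-group discriminator: loadings, centroids, boundary.

    ``gene_loadings`` are axis-1 standard row coordinates (projection weights
    for supplementary profiles); ``group_centroids`` maps group label ->
    axis-1 principal coordinate.  After orientation the reference
    ("symmetric") group centroid is positive.  The model retains the training
    group-mean table so it can be refitted on a gene subset when a test set
    lacks part of the signature.
    """

    gene_loadings: pd.Series
    group_centroids: dict
    eigenvalue: float
    boundary: float
    positive_group: str
    negative_group: str
    training_means: pd.DataFrame
    degenerate: bool = False

    @property
    def gene_ids(self) -> list[str]:
        return list(self.gene_loadings.index)

    # fitted-model conveniences -------------------------------------------

    def project(self, samples: ExpressionMatrix) -> pd.Series:
        return project(self, samples)

    def classify(self, coords) -> pd.Series:
        return classify(self, coords)

    def save(self, path) -> None:
        payload = {
            "group_centroids": self.group_centroids,
            "eigenvalue": self.eigenvalue,
            "boundary": self.boundary,
            "positive_group": self.positive_group,
            "negative_group": self.negative_group,
            "degenerate": self.degenerate,
            "gene_loadings": {g: float(v) for g, v in self.gene_loadings.items()},
            "training_means": {
                col: {g: float(v) for g, v in self.training_means[col].items()}
                for col in self.training_means.columns
            },
        }
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path) -> "BGAModel":
        with open(path, "rt", encoding="utf-8") as fh:
            payload = json.load(fh)
        means = pd.DataFrame(payload["training_means"])
        return cls(
            gene_loadings=pd.Series(payload["gene_loadings"]),
            group_centroids=payload["group_centroids"],
            eigenvalue=payload["eigenvalue"],
            boundary=payload["boundary"],
            positive_group=payload["positive_group"],
            negative_group=payload["negative_group"],
            training_means=means,
            degenerate=payload["degenerate"],
        )


def bga_fit(
    x: ExpressionMatrix,
    groups: pd.Series | dict | None = None,
    reference: str = "SYM",
    shift: str = "error",
) -> BGAModel:
    """Fit the two-group BGA discriminator.

    ``groups`` maps sample id -> group label (exactly two levels); when
    omitted the matrix's condition labels are used.  ``reference`` names the
    group oriented positive (falls back to the lexicographically last label
    if absent).  ``shift="auto"`` adds ``|min|`` to a matrix with negative
    entries before the COA (logged); the default refuses negative input.
    """
    if groups is None:
        if x.conditions is None:
            raise ValidationError("no groups given and matrix has no condition labels")
        groups = x.conditions
    groups = pd.Series(groups).reindex(x.sample_ids)
    if groups.isna().any():
        raise ValidationError("every sample needs a group label")
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValidationError(f"exactly 2 groups required, got {levels}")

    v = x.values
    vmin = v.to_numpy().min()
    if vmin < 0:
        if shift == "auto":
            logger.info("shifting expression by %+.4f to restore nonnegativity", -vmin)
            v = v - vmin
        else:
            raise ValidationError(
                "negative expression values; pass shift='auto' to add |min| globally"
            )

    means = pd.DataFrame(
        {lvl: v[list(groups.index[groups == lvl])].mean(axis=1) for lvl in levels}
    )
    ord_ = coa(means)
    if ord_.n_axes == 0 or ord_.eigenvalues[0] <= 0:
        logger.warning("identical group mean profiles: degenerate BGA model")
        return BGAModel(
            gene_loadings=pd.Series(np.zeros(x.n_genes), index=x.gene_ids),
            group_centroids={lvl: 0.0 for lvl in levels},
            eigenvalue=0.0,
            boundary=0.0,
            positive_group=reference if reference in levels else levels[-1],
            negative_group=[l for l in levels if l != reference][0]
            if reference in levels
            else levels[0],
            training_means=means,
            degenerate=True,
        )

    loadings = pd.Series(ord_.row_standard[:, 0], index=x.gene_ids)
    centroids = {lvl: float(ord_.col_coords[j, 0]) for j, lvl in enumerate(levels)}
    pos = reference if reference in levels else levels[-1]
    neg = [l for l in levels if l != pos][0]
    if centroids[pos] < 0:
        loadings = -loadings
        centroids = {k: -v_ for k, v_ in centroids.items()}
    boundary = 0.5 * (centroids[pos] + centroids[neg])
    return BGAModel(
        gene_loadings=loadings,
        group_centroids=centroids,
        eigenvalue=float(ord_.eigenvalues[0]),
        boundary=boundary,
        positive_group=pos,
        negative_group=neg,
        training_means=means,
    )


def project(model: BGAModel, samples: ExpressionMatrix) -> pd.Series:
    """Axis-1 coordinate of each sample, as a supplementary COA column.

    Each sample's column profile (values normalized to sum 1 over the model
    genes) is averaged over the standard row coordinates — the transition
    formula with 1/sqrt(eigenvalue) scaling.  If the sample matrix lacks some
    model genes the model is refitted on the common subset first (logged).
    """
    if model.degenerate:
        raise DegenerateModelError("cannot project onto a degenerate (zero-inertia) axis")
    have = set(samples.gene_ids)
    if not set(model.gene_ids) <= have:
        common = [g for g in model.gene_ids if g in have]
        if len(common) < 2:
            raise ValidationError("fewer than 2 model genes present in the sample matrix")
        logger.info(
            "refitting BGA on %d/%d genes shared with the test set",
            len(common),
            len(model.gene_ids),
        )
        sub_means = model.training_means.loc[common]
        sub_x = ExpressionMatrix(values=sub_means)
        refit = bga_fit(
            sub_x,
            groups=pd.Series(
                {c: c for c in model.training_means.columns}
            ),
            reference=model.positive_group,
        )
        model = refit
    v = samples.values.loc[model.gene_ids]
    totals = v.sum(axis=0)
    if (totals <= 0).any():
        raise ValidationError("sample with nonpositive profile total")
    profiles = v / totals
    coords = profiles.T @ model.gene_loadings.loc[model.gene_ids]
    return pd.Series(coords, index=samples.sample_ids, name="axis1")


def classify(model: BGAModel, coords) -> pd.Series:
    """Label each coordinate by its side of the decision boundary.

    The positive (symmetric-reference) side maps to "symmetric-character",
    the other to "asymmetric-character"; coordinates exactly on the boundary
    are labeled symmetric-character and logged.
    """
    coords = pd.Series(coords, dtype=float)
    if not np.isfinite(coords.to_numpy()).all():
        raise ValidationError("non-finite coordinate")
    on_boundary = coords == model.boundary
    if on_boundary.any():
        logger.warning(
            "%d sample(s) exactly on the boundary; labeled %s",
            int(on_boundary.sum()),
            SYMMETRIC_LABEL,
        )
    labels = np.where(coords >= model.boundary, SYMMETRIC_LABEL, ASYMMETRIC_LABEL)
    return pd.Series(labels, index=coords.index, name="label")


def separation_pvalue(coords_a, coords_b) -> tuple[float, float]:
    """Two-sample pooled-variance Student's t on axis coordinates.

    Returns ``(t, two-sided p)``.  Degenerate zero-variance cases: equal
    means give p = 1; unequal means with zero pooled variance give p = 0
    (logged).
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValidationError("both groups need at least one coordinate")
    pooled_ss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    if pooled_ss == 0 or len(a) + len(b) < 3:
        if math.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        logger.warning("zero within-group variance with unequal means; p = 0")
        return math.inf if a.mean() > b.mean() else -math.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def separation_distance(
    coords, groups, negative_group: str, positive_group: str
) -> float:
    """Signed difference of group mean coordinates.

    Positive when the two groups are ordered like the training reference
    (``negative_group`` below ``positive_group`` on the axis, i.e. the
    asymmetric-to-symmetric direction).
    """
    coords = pd.Series(coords, dtype=float)
    groups = pd.Series(groups).reindex(coords.index)
    for g in (negative_group, positive_group):
        if not (groups == g).any():
            raise ValidationError(f"group {g!r} absent from coordinates")
    pos_mean = coords[groups == positive_group].mean()
    neg_mean = coords[groups == negative_group].mean()
    return float(pos_mean - neg_mean)


def merge_symmetric_labels(
    conditions: pd.Series,
    symmetric=("SYM", "p53SYM"),
    merged: str = "SYM",
) -> pd.Series:
    """Training-contrast helper: collapse the symmetric states into one group."""
    out = conditions.copy().astype(str)
    out[out.isin(symmetric)] = merged
    return out


def signature_bga(
    x: ExpressionMatrix,
    signature: GeneSet,
    groups: pd.Series | None = None,
    reference: str = "SYM",
) -> BGAModel:
    """Fit the discriminator on the signature genes of a training matrix."""
    x_sub, _, _ = match_genes(x, signature)
    if groups is None:
        groups = merge_symmetric_labels(x.conditions)
    return bga_fit(x_sub, groups=groups, reference=reference)
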