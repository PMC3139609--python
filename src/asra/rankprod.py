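"""Rank-products differential expression with permutation-based pfp control.

For a two-condition comparison with n1 and n2 replicates, all K = n1 x n2
one-vs-one difference lists are formed.  In each list genes are ranked by
decreasing log2 difference (rank 1 = most up-regulated) and, separately, by
increasing difference.  A gene's rank product is the geometric mean of its K
ranks; genes consistently near the top of every list get statistics close
to 1.  Significance is controlled through the percent-false-positive (pfp)
estimate: null rank products are generated by replacing each list's rank
vector with an independent uniform random permutation, the expected number of
null statistics at or below the observed one is computed, and pfp is that
expectation divided by the gene's rank among observed statistics (the rank-
products analogue of a false discovery rate; values may exceed 1 and are not
clipped).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_model import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class RankLists:
    """Per-list gene ranks for one two-condition comparison.

    ``ranks_up[k, g]`` is gene ``g``'s rank in list ``k`` when sorted by
    decreasing difference (condition1 - condition2); ``ranks_down`` sorts by
    increasing difference.  Without ties each list's ranks are a permutation
    of 1..G; tied differences share their average rank.
    """

    gene_ids: list
    ranks_up: np.ndarray   # (K, G)
    ranks_down: np.ndarray

    def __post_init__(self) -> None:
        for name in ("ranks_up", "ranks_down"):
            r = getattr(self, name)
            if r.ndim != 2 or r.shape[1] != len(self.gene_ids):
                raise ValidationError(f"{name} must be (K, G)")

    @property
    def K(self) -> int:
        return self.ranks_up.shape[0]

    @property
    def G(self) -> int:
        return self.ranks_up.shape[1]


@dataclass
class DifferentialResult:
    """Per-gene rank-product statistics for one comparison."""

    gene_ids: list
    rp_up: np.ndarray
    rp_down: np.ndarray
    pfp_up: np.ndarray
    pfp_down: np.ndarray
    fc: np.ndarray          # mean log2 difference, condition1 - condition2
    sig_up: np.ndarray
    sig_down: np.ndarray
    cutoff: float
    comparison: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rp_up": self.rp_up,
                "pfp_up": self.pfp_up,
                "rp_down": self.rp_down,
                "pfp_down": self.pfp_down,
                "fc": self.fc,
                "sig_up": self.sig_up,
                "sig_down": self.sig_down,
            },
            index=pd.Index(self.gene_ids, name="gene_id"),
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.6g")


def _ranks_by_decreasing(d: np.ndarray) -> np.ndarray:
    """Rank 1 = largest value; tied values share their average rank.

    Average ranks keep tied genes exchangeable: a positional tie-break would
    hand the same gene the best rank of its tie block in *every* list,
    manufacturing spurious cross-list consistency (severe for low-noise data
    where undifferentiated genes tie at a difference of zero).
    """
    return rankdata(-d, method="average")


def _ranks_by_decreasing_fast(d: np.ndarray) -> np.ndarray:
    """Positional ranks (no tie handling) for continuous null draws."""
    order = np.argsort(-d, kind="stable")
    ranks = np.empty(d.shape[0], dtype=np.int64)
    ranks[order] = np.arange(1, d.shape[0] + 1)
    return ranks


def pairwise_difference_lists(
    x: ExpressionMatrix, g1: str, g2: str
) -> RankLists:
    """Build the K = n1 x n2 one-vs-one difference rank lists for g1 vs g2."""
    s1 = x.samples_of(g1)
    s2 = x.samples_of(g2)
    if x.n_genes < 2:
        raise ValidationError("need at least 2 genes to rank")
    v = x.values
    ups, downs = [], []
    for i in s1:
        for j in s2:
            d = v[i].to_numpy() - v[j].to_numpy()
            ups.append(_ranks_by_decreasing(d))
            downs.append(_ranks_by_decreasing(-d))
    return RankLists(
        gene_ids=x.gene_ids,
        ranks_up=np.vstack(ups),
        ranks_down=np.vstack(downs),
    )


def rank_product(r: RankLists, direction: str) -> np.ndarray:
    """Geometric mean rank per gene for ``direction`` in {"up", "down"}."""
    if direction not in ("up", "down"):
        raise ValidationError("direction must be 'up' or 'down'")
    ranks = r.ranks_up if direction == "up" else r.ranks_down
    return np.exp(np.log(ranks.astype(float)).mean(axis=0))


def _null_rank_products(G: int, K: int, B: int, rng) -> np.ndarray:
    """B x G null statistics; each list's ranks are an independent permutation."""
    out = np.empty((B, G))
    for b in range(B):
        logsum = np.zeros(G)
        for _ in range(K):
            perm = rng.permutation(G) + 1
            logsum += np.log(perm)
        out[b] = np.exp(logsum / K)
    return out


def _null_rank_products_within_array(
    v1: np.ndarray, v2: np.ndarray, B: int, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Null rank products preserving the comparison's dependence structure.

    Each permutation round shuffles the gene assignment *within every array*
    (column) independently and recomputes all K pairwise difference lists.
    Because a shuffled array contributes to several lists, the correlation
    between lists that share an array — which the independent-per-list null
    ignores — is carried into the null.  Returns pooled (B*G,) up and down
    null statistics.
    """
    G = v1.shape[0]
    K = v1.shape[1] * v2.shape[1]
    null_up = np.empty((B, G))
    null_down = np.empty((B, G))
    for b in range(B):
        s1 = np.empty_like(v1)
        s2 = np.empty_like(v2)
        for j in range(v1.shape[1]):
            s1[:, j] = v1[rng.permutation(G), j]
        for j in range(v2.shape[1]):
            s2[:, j] = v2[rng.permutation(G), j]
        logsum_up = np.zeros(G)
        logsum_down = np.zeros(G)
        for i in range(v1.shape[1]):
            for j in range(v2.shape[1]):
                ranks = _ranks_by_decreasing_fast(s1[:, i] - s2[:, j]).astype(float)
                logsum_up += np.log(ranks)
                logsum_down += np.log(G + 1 - ranks)
        null_up[b] = np.exp(logsum_up / K)
        null_down[b] = np.exp(logsum_down / K)
    return null_up.ravel(), null_down.ravel()


def estimate_pfp(
    r: RankLists,
    rp_obs: np.ndarray,
    B: int = 100,
    seed: int = 0,
    exhaustive: bool = False,
) -> np.ndarray:
    """Percent-false-positive estimate for observed rank products.

    ``pfp_g = E_g / rho_g`` where ``E_g`` is the expected count of null rank
    products <= ``rp_obs_g`` per permutation round and ``rho_g`` the (average,
    ascending) rank of ``rp_obs_g`` among the observed statistics.  With
    ``exhaustive=True`` the null is the complete set of per-list permutation
    assignments (feasible only for toy instances), replacing sampling.
    """
    G, K = r.G, r.K
    rp_obs = np.asarray(rp_obs, dtype=float)
    if exhaustive:
        if math.factorial(G) ** K > 200_000:
            raise ValidationError("exhaustive enumeration only supported for toy instances")
        perms = list(itertools.permutations(range(1, G + 1)))
        null = []
        for combo in itertools.product(perms, repeat=K):
            arr = np.array(combo, dtype=float)  # (K, G)
            null.append(np.exp(np.log(arr).mean(axis=0)))
        null = np.asarray(null)
        n_rounds = len(null)
    else:
        if B < 1:
            raise ValidationError("permutation count B must be >= 1")
        rng = np.random.default_rng(seed)
        null = _null_rank_products(G, K, B, rng)
        n_rounds = B
    return _pfp_from_pooled_null(null.ravel(), rp_obs, n_rounds)


def _pfp_from_pooled_null(null_values: np.ndarray, rp_obs: np.ndarray, n_rounds: int) -> np.ndarray:
    pooled = np.sort(null_values)
    counts = np.searchsorted(pooled, rp_obs, side="right")
    expected = counts / n_rounds
    rho = rankdata(rp_obs, method="average")
    return expected / rho


def call_differential(
    x: ExpressionMatrix,
    g1: str,
    g2: str,
    cutoff: float = 0.05,
    B: int = 100,
    seed: int = 0,
    null: str = "within-array",
) -> DifferentialResult:
    """Full rank-products call for condition ``g1`` vs ``g2``.

    Significance is ``pfp <= cutoff`` per direction; in the (degenerate) case
    where a gene would be called in both directions, the direction with the
    smaller rank product wins.  ``fc`` is the difference of condition mean
    log2 values (g1 - g2).

    ``null`` selects the permutation scheme for the pfp estimate:
    ``"within-array"`` (default) shuffles genes within each array and
    recomputes the lists, preserving the correlation between lists that share
    an array; ``"independent-lists"`` permutes each list's rank vector
    independently (the original rank-products null, anti-conservative for
    pairwise lists built from shared arrays).
    """
    if not 0 <= cutoff:
        raise ValidationError("cutoff must be nonnegative")
    if B < 1:
        raise ValidationError("permutation count B must be >= 1")
    lists = pairwise_difference_lists(x, g1, g2)
    rp_up = rank_product(lists, "up")
    rp_down = rank_product(lists, "down")
    seeds = np.random.SeedSequence(seed).generate_state(2)
    if null == "within-array":
        rng = np.random.default_rng(int(seeds[0]))
        v1 = x.values[x.samples_of(g1)].to_numpy()
        v2 = x.values[x.samples_of(g2)].to_numpy()
        null_up, null_down = _null_rank_products_within_array(v1, v2, B, rng)
        pfp_up = _pfp_from_pooled_null(null_up, rp_up, B)
        pfp_down = _pfp_from_pooled_null(null_down, rp_down, B)
    elif null == "independent-lists":
        pfp_up = estimate_pfp(lists, rp_up, B=B, seed=int(seeds[0]))
        pfp_down = estimate_pfp(lists, rp_down, B=B, seed=int(seeds[1]))
    else:
        raise ValidationError(f"unknown null scheme {null!r}")
    if cutoff == 0:
        # a sampled pfp of exactly 0 only means "< 1/(B*rho)"; a zero cutoff
        # therefore disables calling rather than admitting resolution artifacts
        logger.warning("pfp cutoff 0: no gene can be called significant")
        sig_up = np.zeros(lists.G, dtype=bool)
        sig_down = np.zeros(lists.G, dtype=bool)
    else:
        sig_up = pfp_up <= cutoff
        sig_down = pfp_down <= cutoff
    both = sig_up & sig_down
    if both.any():
        up_wins = rp_up[both] <= rp_down[both]
        sig_up_b = sig_up[both].copy()
        sig_down_b = sig_down[both].copy()
        sig_up_b[:] = up_wins
        sig_down_b[:] = ~up_wins
        sig_up[both] = sig_up_b
        sig_down[both] = sig_down_b
    fc = (
        x.values[x.samples_of(g1)].mean(axis=1) - x.values[x.samples_of(g2)].mean(axis=1)
    ).to_numpy()
    return DifferentialResult(
        gene_ids=x.gene_ids,
        rp_up=rp_up,
        rp_down=rp_down,
        pfp_up=pfp_up,
        pfp_down=pfp_down,
        fc=fc,
        sig_up=sig_up,
        sig_down=sig_down,
        cutoff=cutoff,
        comparison=f"{g1} vs {g2}",
    )
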