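"""Gene-set level inference on ranked probe lists.

Three tools:

* a weighted Kolmogorov–Smirnov-like running-sum enrichment score over a
  ranked list, with a gene-permutation null giving normalized enrichment
  scores (NES), nominal p, FDR q and FWER p per set;
* a rank-position set test (one-sided Wilcoxon rank-sum of member ranks vs
  non-member ranks) for "are these transcripts near the top of the list";
* construction of gene sets from IUPAC degenerate motifs matched against
  3'UTR sequences.

The permutation null resamples set members from the ranked universe (gene
permutation). With five-vs-five samples a phenotype-relabeling null has only
252 distinct relabelings — far too few to resolve FDR q-values — so member
resampling is the default; phenotype permutation is available via
``mode="phenotype"`` when replicate columns are supplied.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import stats

from .arrayio import GeneSetCollection
from .ripstats import DifferentialResult

IUPAC_DNA = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

#: histone 3'UTR stem-loop-overlapping motifs used as built-in gene sets
HISTONE_MOTIFS = ("KRCTCNNNNMANAGC", "TTTNNANAGCYR")


@dataclass
class RankedList:
    """Ids ordered by descending score; ties broken by id (deterministic)."""

    ids: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.ids) != len(self.scores):
            raise ValueError("ids and scores must align")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be non-increasing")
        if len(set(self.ids.tolist())) != len(self.ids):
            raise ValueError("duplicate ids in ranked list")

    def __len__(self) -> int:
        return len(self.ids)

    def positions_of(self, members) -> np.ndarray:
        index = {pid: i for i, pid in enumerate(self.ids)}
        return np.array(sorted(index[m] for m in members if m in index), dtype=int)


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    nominal_p: float
    fdr_q: float
    fwer_p: float
    leading_edge_size: int
    set_size: int


def rank_by_score(ids, scores) -> RankedList:
    """Build a RankedList from unordered (id, score) pairs.

    Descending score; exact ties fall back to lexicographic id order so the
    output is independent of input order.
    """
    ids = np.asarray(ids, dtype=object)
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    order = sorted(range(len(ids)), key=lambda i: (-scores[i], str(ids[i])))
    return RankedList(ids[order], scores[order])


def rank_by_key(diff: DifferentialResult, key: str = "t_score") -> RankedList:
    """Rank probes by a DifferentialResult column (t_score or log_fold_change)."""
    return rank_by_score(diff.probe_ids, getattr(diff, key))


def gsea_enrichment_score(ranked: RankedList, set_members, p: float = 1.0
                          ) -> tuple[float, np.ndarray, list]:
    """Running-sum enrichment score of a set in a ranked list.

    At member positions the sum gains |score|^p normalized by the members'
    total weight; elsewhere it loses 1/(N - N_set). ES is the signed extremum
    of the running sum; the leading edge holds the members at or before the
    extremum (positive ES) or at/after it (negative ES).
    """
    hit_pos = ranked.positions_of(set_members)
    if len(hit_pos) == 0:
        raise ValueError("no overlap between set and ranked list")
    n = len(ranked)
    is_hit = np.zeros(n, dtype=bool)
    is_hit[hit_pos] = True
    w = np.abs(ranked.scores) ** p
    w_hit = np.where(is_hit, w, 0.0)
    total = w_hit.sum()
    # all member weights zero (p > 0 with zero scores): hits contribute
    # nothing and the sum drifts to -1 — the set is uninformative
    increments = w_hit / total if total > 0 else np.zeros(n)
    n_miss = n - len(hit_pos)
    miss_step = 1.0 / n_miss if n_miss > 0 else 0.0
    steps = increments - np.where(is_hit, 0.0, miss_step)
    running = np.cumsum(steps)
    extreme = int(np.argmax(np.abs(running)))
    es = float(running[extreme])
    if es >= 0:
        leading = [ranked.ids[i] for i in hit_pos if i <= extreme]
    else:
        leading = [ranked.ids[i] for i in hit_pos if i >= extreme]
    return es, running, leading


def _es_from_positions(pos_sorted: np.ndarray, weights: np.ndarray,
                       n: int) -> np.ndarray:
    """Vectorized ES for many permutations given sorted hit positions.

    ``pos_sorted``: (n_perm, k) sorted positions; ``weights``: per-position
    |score|^p over the whole list. Evaluates the running sum only at its
    candidate extrema (just before and at each hit).
    """
    n_perm, k = pos_sorted.shape
    w = weights[pos_sorted]
    tot = w.sum(axis=1, keepdims=True)
    zero_tot = tot[:, 0] == 0
    safe_tot = np.where(tot > 0, tot, 1.0)
    cum = np.cumsum(w, axis=1) / safe_tot
    j = np.arange(k)
    miss = (pos_sorted - j) / max(n - k, 1)
    after = cum - miss          # running sum at each hit
    before = after - w / safe_tot  # running sum just before each hit
    hi = after.max(axis=1)
    lo = before.min(axis=1)
    es = np.where(hi >= -lo, hi, lo)
    # zero-weight rows decay monotonically to -1 at the end of the list
    return np.where(zero_tot, -1.0, es)


def gsea_significance(ranked: RankedList, collection: GeneSetCollection,
                      n_perm: int = 1000, p: float = 1.0, seed: int = 0,
                      mode: str = "gene", phenotype_data: tuple | None = None
                      ) -> list[EnrichmentResult]:
    """Permutation significance for every set in a collection.

    NES is ES divided by the mean |null ES| of matching sign; nominal p uses
    the add-one convention (1 + #{null >= obs}) / (n_perm + 1) on the
    matching-sign null. FDR q pools sign-matched normalized null scores
    across sets (standard NES-based procedure); FWER p comes from the
    per-permutation extreme-NES distribution. Deterministic under ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    n = len(ranked)
    rng = np.random.default_rng(seed)
    weights = np.abs(ranked.scores) ** p

    names, obs_es, sizes, leading_sizes = [], [], [], []
    for name in collection.names():
        members = collection.members(name)
        pos = ranked.positions_of(members)
        if len(pos) == 0:
            raise ValueError(f"set {name!r} has no overlap with the ranked list")
        if len(pos) >= n:
            raise ValueError(f"set {name!r} covers the whole universe")
        es, _, leading = gsea_enrichment_score(ranked, members, p=p)
        names.append(name)
        obs_es.append(es)
        sizes.append(len(pos))
        leading_sizes.append(len(leading))
    obs_es = np.asarray(obs_es)

    if mode == "phenotype":
        null_es = _phenotype_null(ranked, collection, names, n_perm, p,
                                  rng, phenotype_data)
    else:
        # one gene-label permutation per iteration, shared by all sets: a set
        # of size k lands on positions perm[:k], so equal-size sets see
        # identical nulls within a permutation, as label permutation implies
        max_k = max(sizes)
        perms = np.argsort(rng.random((n_perm, n)), axis=1)[:, :max_k]
        null_es = np.empty((len(names), n_perm))
        es_by_size: dict[int, np.ndarray] = {}
        for si, k in enumerate(sizes):
            if k not in es_by_size:
                pos = np.sort(perms[:, :k], axis=1)
                es_by_size[k] = _es_from_positions(pos, weights, n)
            null_es[si] = es_by_size[k]

    return _summarize_permutations(names, obs_es, sizes, leading_sizes,
                                   null_es, n_perm)


def _phenotype_null(ranked, collection, names, n_perm, p, rng, phenotype_data):
    """Null ES from relabeling IP/mock columns and re-ranking each time."""
    if phenotype_data is None:
        raise ValueError("phenotype mode needs (probe_ids, ip_columns, mock_columns)")
    from .ripstats import t_statistics

    probe_ids, ip, mock = phenotype_data
    both = np.hstack([ip, mock])
    n1 = ip.shape[1]
    null_es = np.empty((len(names), n_perm))
    for b in range(n_perm):
        idx = rng.permutation(both.shape[1])
        d = t_statistics(probe_ids, both[:, idx[:n1]], both[:, idx[n1:]])
        r = rank_by_score(d.probe_ids, d.t_score)
        for si, name in enumerate(names):
            null_es[si, b] = gsea_enrichment_score(r, collection.members(name), p=p)[0]
    return null_es


def _summarize_permutations(names, obs_es, sizes, leading_sizes, null_es,
                            n_perm) -> list[EnrichmentResult]:
    n_sets = len(names)
    nes = np.empty(n_sets)
    null_nes = np.empty_like(null_es)
    nominal_p = np.empty(n_sets)
    for i in range(n_sets):
        null = null_es[i]
        pos_mean = null[null > 0].mean() if np.any(null > 0) else 1.0
        neg_mean = np.abs(null[null < 0]).mean() if np.any(null < 0) else 1.0
        null_nes[i] = np.where(null >= 0, null / pos_mean, null / neg_mean)
        nes[i] = obs_es[i] / pos_mean if obs_es[i] >= 0 else obs_es[i] / neg_mean
        if obs_es[i] >= 0:
            nominal_p[i] = (1 + np.sum(null >= obs_es[i])) / (n_perm + 1)
        else:
            nominal_p[i] = (1 + np.sum(null <= obs_es[i])) / (n_perm + 1)

    # FDR: pooled sign-matched normalized null scores vs observed NES
    pooled = null_nes.ravel()
    fdr_q = np.empty(n_sets)
    for i in range(n_sets):
        if nes[i] >= 0:
            num = np.mean(pooled[pooled >= 0] >= nes[i]) if np.any(pooled >= 0) else 1.0
            den = np.mean(nes[nes >= 0] >= nes[i])
        else:
            num = np.mean(pooled[pooled < 0] <= nes[i]) if np.any(pooled < 0) else 1.0
            den = np.mean(nes[nes < 0] <= nes[i])
        fdr_q[i] = min(1.0, num / max(den, 1.0 / n_sets / n_perm))

    # FWER: distribution of the most extreme same-sign NES per permutation
    max_pos = null_nes.max(axis=0)
    min_neg = null_nes.min(axis=0)
    fwer = np.empty(n_sets)
    for i in range(n_sets):
        if nes[i] >= 0:
            fwer[i] = (1 + np.sum(max_pos >= nes[i])) / (1 + n_perm)
        else:
            fwer[i] = (1 + np.sum(min_neg <= nes[i])) / (1 + n_perm)

    return [EnrichmentResult(set_name=names[i], es=float(obs_es[i]),
                             nes=float(nes[i]), nominal_p=float(nominal_p[i]),
                             fdr_q=float(fdr_q[i]), fwer_p=float(fwer[i]),
                             leading_edge_size=int(leading_sizes[i]),
                             set_size=int(sizes[i]))
            for i in range(n_sets)]


def rank_position_test(ranked: RankedList, set_members,
                       alternative: str = "enriched_at_top",
                       exact_limit: int = 10**6) -> tuple[float, float]:
    """One-sided Wilcoxon rank-sum: are set members near the top of the list?

    The statistic is the members' rank sum (rank 1 = top of the list). The
    p-value is exact (full enumeration of the rank-sum distribution) when
    C(N, n_set) <= ``exact_limit``, otherwise the normal approximation with
    continuity correction.
    """
    pos = ranked.positions_of(set_members)
    if len(pos) == 0:
        raise ValueError("empty intersection between set and ranked list")
    n = len(ranked)
    k = len(pos)
    if k >= n:
        raise ValueError("set must be a proper subset of the ranked list")
    member_ranks = pos + 1.0
    other = np.setdiff1d(np.arange(1.0, n + 1.0), member_ranks)
    scipy_alt = "less" if alternative == "enriched_at_top" else "greater"
    method = "exact" if comb(n, k) <= exact_limit else "asymptotic"
    res = stats.mannwhitneyu(member_ranks, other, alternative=scipy_alt,
                             method=method, use_continuity=True)
    statistic = float(member_ranks.sum())
    return statistic, float(res.pvalue)


def iupac_to_regex(pattern: str) -> re.Pattern:
    """Compile an IUPAC degenerate nucleotide pattern to a regex."""
    parts = []
    for ch in pattern.upper():
        if ch == "U":
            ch = "T"
        if ch not in IUPAC_DNA:
            raise ValueError(f"invalid IUPAC nucleotide code: {ch!r}")
        allowed = IUPAC_DNA[ch]
        parts.append(allowed if len(allowed) == 1 else f"[{allowed}]")
    return re.compile("".join(parts))


def motif_gene_set(sequences: dict[str, str], iupac_pattern: str) -> list[str]:
    """Ids of sequences with >= 1 sense-strand match of a degenerate motif.

    Case-insensitive; U is treated as T. Order follows the input mapping.
    """
    rx = iupac_to_regex(iupac_pattern)
    members = []
    for sid, seq in sequences.items():
        s = seq.upper().replace("U", "T")
        if rx.search(s):
            members.append(sid)
    return members
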