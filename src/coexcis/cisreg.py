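"""Genome-scale cis-regulatory element discovery.

Pipeline: (1) an internal seed-and-extend ungapped local aligner finds
subsequences shared between promoters (identity and Karlin-Altschul E-value
filters); (2) every 6-mer inside a passing alignment's query span becomes a
candidate binding site, subject to a homopolymer filter; (3) each candidate
is scored by promoter bootstrap enrichment — resample cluster and background
promoter sets with replacement, compare mean occurrences per promoter, and
report the fold ratio (cluster mean / background mean) with a bootstrap-t
p-value; (4) candidates are tiered at fold >= 2, 3, 4 and can be benchmarked
against a list of known elements (nTP / nFP / precision).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import ttest_ind

from .datasets import KnownElementList, PromoterSet

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# alignment


@dataclass
class AlignParams:
    """Ungapped seed-and-extend parameters (defaults emulate a word-7
    nucleotide search with +1/-2 scoring)."""

    word_size: int = 7
    match: int = 1
    mismatch: int = -2
    x_drop: int = 10
    ka_k: float = 0.46


@dataclass
class LocalAlignmentHit:
    query_id: str
    subject_id: str
    query_span: tuple[int, int]    # 0-based half-open
    subject_span: tuple[int, int]
    length: int
    identity: float
    score: int
    e_value: float = float("inf")


def karlin_altschul_lambda(match: int = 1, mismatch: int = -2) -> float:
    """Positive root of sum_ij p_i p_j exp(lambda * s(i, j)) = 1 under uniform
    base composition: (1/4) e^(lambda*match) + (3/4) e^(lambda*mismatch) = 1."""
    if match <= 0:
        raise ValueError("match score must be positive")
    expected = 0.25 * match + 0.75 * mismatch
    if expected >= 0:
        raise ValueError("expected score must be negative for local statistics")

    def f(lam: float) -> float:
        return 0.25 * np.exp(lam * match) + 0.75 * np.exp(lam * mismatch) - 1.0

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
    return float(brentq(f, 1e-9, hi))


def karlin_altschul_evalue(
    score: float, m: int, n: int, match: int = 1, mismatch: int = -2, k: float = 0.46
) -> float:
    """E = K * m * n * exp(-lambda * score) for an ungapped local alignment."""
    if score <= 0:
        raise ValueError("score must be positive")
    lam = karlin_altschul_lambda(match, mismatch)
    return float(k * m * n * np.exp(-lam * score))


def _extend(
    q: str, s: str, qi: int, si: int, w: int, params: AlignParams
) -> tuple[int, int, int, int, int, int]:
    """Extend an exact word seed in both directions with X-drop termination.

    Returns (q_start, q_end, s_start, s_end, score, matches).
    """
    score = w * params.match
    matches = w
    best_score = score
    # right extension
    best_qe, best_se, best_m = qi + w, si + w, matches
    cur_m = matches
    i, j = qi + w, si + w
    cur = score
    while i < len(q) and j < len(s):
        cur += params.match if q[i] == s[j] else params.mismatch
        cur_m += 1 if q[i] == s[j] else 0
        i += 1
        j += 1
        if cur > best_score:
            best_score, best_qe, best_se, best_m = cur, i, j, cur_m
        elif best_score - cur > params.x_drop:
            break
    # left extension
    score = best_score
    matches = best_m
    best_qs, best_ss = qi, si
    i, j = qi - 1, si - 1
    cur = score
    cur_m = matches
    while i >= 0 and j >= 0:
        cur += params.match if q[i] == s[j] else params.mismatch
        cur_m += 1 if q[i] == s[j] else 0
        if cur > score:
            score, best_qs, best_ss, matches = cur, i, j, cur_m
        elif score - cur > params.x_drop:
            break
        i -= 1
        j -= 1
    return best_qs, best_qe, best_ss, best_se, score, matches


def seed_extend_align(
    query_id: str,
    query: str,
    db: PromoterSet,
    params: AlignParams | None = None,
) -> list[LocalAlignmentHit]:
    """Ungapped local alignment of one query against a promoter database.

    Exact ``word_size`` seeds are located via a k-mer index of the database,
    extended in both directions with X-drop termination, and overlapping hits
    to the same subject are merged keeping the higher score.  Self-hits (same
    gene ID) are excluded.  E-values use search space = query length x total
    database length.
    """
    params = params or AlignParams()
    w = params.word_size
    if len(query) < w:
        raise ValueError("query shorter than word size")
    query = query.upper()
    index: dict[str, list[tuple[str, int]]] = {}
    for sid, seq in db.records.items():
        if sid == query_id:
            continue
        for p in range(len(seq) - w + 1):
            word = seq[p : p + w]
            if "N" in word:
                continue
            index.setdefault(word, []).append((sid, p))
    total_db = sum(len(s) for sid, s in db.records.items() if sid != query_id)
    # best hit per (subject, diagonal) to avoid re-extending the same alignment
    best: dict[str, dict[tuple[int, int, int, int], LocalAlignmentHit]] = {}
    seen_diag: dict[tuple[str, int], list[tuple[int, int]]] = {}
    for qi in range(len(query) - w + 1):
        word = query[qi : qi + w]
        if "N" in word:
            continue
        for sid, si in index.get(word, ()):  # each seed
            diag = qi - si
            spans = seen_diag.setdefault((sid, diag), [])
            if any(a <= qi < b for a, b in spans):
                continue  # seed inside an alignment already found on this diagonal
            qs, qe, ss, se, score, matches = _extend(
                query, db.records[sid], qi, si, w, params
            )
            spans.append((qs, qe))
            length = qe - qs
            hit = LocalAlignmentHit(
                query_id=query_id,
                subject_id=sid,
                query_span=(qs, qe),
                subject_span=(ss, se),
                length=length,
                identity=matches / length,
                score=score,
                e_value=karlin_altschul_evalue(
                    score, len(query), total_db, params.match, params.mismatch, params.ka_k
                ),
            )
            best.setdefault(sid, {})
            key = (qs, qe, ss, se)
            prev = best[sid].get(key)
            if prev is None or hit.score > prev.score:
                best[sid][key] = hit
    # merge overlapping hits to the same subject, keeping the higher score
    hits: list[LocalAlignmentHit] = []
    for sid, by_span in best.items():
        ranked = sorted(by_span.values(), key=lambda h: -h.score)
        kept: list[LocalAlignmentHit] = []
        for h in ranked:
            if any(
                h.query_span[0] < k2.query_span[1]
                and k2.query_span[0] < h.query_span[1]
                and h.subject_span[0] < k2.subject_span[1]
                and k2.subject_span[0] < h.subject_span[1]
                for k2 in kept
            ):
                continue
            kept.append(h)
        hits.extend(kept)
    hits.sort(key=lambda h: (h.e_value, h.subject_id, h.query_span))
    return hits


# ---------------------------------------------------------------------------
# k-mer candidates


def homopolymer_filter(kmer: str, k: int = 6) -> bool:
    """Keep a k-mer iff its longest single-nucleotide run is at most 4."""
    kmer = kmer.upper()
    if len(kmer) != k or set(kmer) - set("ACGT"):
        raise ValueError(f"expected a length-{k} ACGT string, got {kmer!r}")
    run = best = 1
    for a, b in zip(kmer, kmer[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best <= 4


@dataclass
class KmerCandidateSet:
    """Candidate binding-site k-mers with per-k-mer supporting hit counts."""

    kmers: set[str]
    provenance: dict[str, int] = field(default_factory=dict)
    k: int = 6

    def __post_init__(self) -> None:
        for kmer in self.kmers:
            if len(kmer) != self.k:
                raise ValueError(f"k-mer {kmer!r} is not length {self.k}")
            if not homopolymer_filter(kmer, self.k):
                raise ValueError(f"k-mer {kmer!r} fails the homopolymer filter")

    def __len__(self) -> int:
        return len(self.kmers)

    def __iter__(self):
        return iter(sorted(self.kmers))


def shared_kmer_candidates(
    promoters: PromoterSet,
    min_identity: float = 0.75,
    max_evalue: float = 1e-4,
    k: int = 6,
    params: AlignParams | None = None,
) -> KmerCandidateSet:
    """All-vs-all alignment, then k-mer extraction from passing hits.

    Each promoter queries the full set; hits with identity >= ``min_identity``
    and E <= ``max_evalue`` contribute every k-window of their query-side
    aligned span (windows containing N are skipped).  Homopolymeric k-mers
    are dropped; provenance counts the number of supporting hits per k-mer.
    """
    if len(promoters) < 2:
        raise ValueError("need at least 2 promoters")
    kmers: set[str] = set()
    provenance: dict[str, int] = {}
    for qid in sorted(promoters.records):
        query = promoters.records[qid]
        for hit in seed_extend_align(qid, query, promoters, params):
            if hit.identity < min_identity or hit.e_value > max_evalue:
                continue
            qs, qe = hit.query_span
            seen_in_hit: set[str] = set()
            for p in range(qs, qe - k + 1):
                kmer = query[p : p + k]
                if "N" in kmer:
                    continue
                if not homopolymer_filter(kmer, k):
                    continue
                seen_in_hit.add(kmer)
            for kmer in seen_in_hit:
                kmers.add(kmer)
                provenance[kmer] = provenance.get(kmer, 0) + 1
    return KmerCandidateSet(kmers, provenance, k)


def direct_kmer_candidates(
    promoters: PromoterSet, k: int = 6, min_promoter_fraction: float = 0.8
) -> KmerCandidateSet:
    """Sliding-window candidates: k-mers present in at least a fraction of the
    promoters.

    This mode skips the alignment stage; it suits promoter sets without long
    shared homology blocks (e.g. synthetic uniform backgrounds) where the
    signal is purely the occurrence-rate enrichment of short motifs.
    """
    if len(promoters) < 2:
        raise ValueError("need at least 2 promoters")
    support: dict[str, int] = {}
    for seq in promoters.records.values():
        present = set()
        for p in range(len(seq) - k + 1):
            kmer = seq[p : p + k]
            if "N" not in kmer:
                present.add(kmer)
        for kmer in present:
            support[kmer] = support.get(kmer, 0) + 1
    need = max(2, int(np.ceil(min_promoter_fraction * len(promoters))))
    kept = {
        kmer: c
        for kmer, c in support.items()
        if c >= need and homopolymer_filter(kmer, k)
    }
    return KmerCandidateSet(set(kept), kept, k)


# ---------------------------------------------------------------------------
# occurrence counting and bootstrap enrichment


def count_occurrences(kmer: str, seq: str, both_strands: bool = False) -> int:
    """Overlapping occurrences of ``kmer`` in ``seq`` (forward strand; with
    ``both_strands`` the reverse complement is added unless the k-mer is
    palindromic, which would double-count)."""
    kmer, seq = kmer.upper(), seq.upper()
    total = _count_forward(kmer, seq)
    if both_strands:
        rc = reverse_complement(kmer)
        if rc != kmer:
            total += _count_forward(rc, seq)
    return total


def _count_forward(kmer: str, seq: str) -> int:
    count = start = 0
    while True:
        p = seq.find(kmer, start)
        if p < 0:
            return count
        count += 1
        start = p + 1


@dataclass
class EnrichmentRecord:
    kmer: str
    cluster_mean: float
    background_mean: float
    fold_ratio: float | None  # None when background_mean == 0
    t_statistic: float
    p_value: float
    n_boot: int
    seed: int
    support: int = 0
    tiers: tuple[int, ...] = ()


def _occurrence_vector(
    kmer: str, promoters: PromoterSet, both_strands: bool
) -> np.ndarray:
    return np.array(
        [count_occurrences(kmer, s, both_strands) for s in promoters.records.values()],
        dtype=float,
    )


def bootstrap_enrichment(
    kmer: str,
    cluster: PromoterSet,
    background: PromoterSet,
    n_boot: int = 1000,
    seed: int = 0,
    both_strands: bool = False,
) -> EnrichmentRecord:
    """Promoter-bootstrap enrichment of one k-mer.

    Draws ``n_boot`` bootstrap replicates of size m = |cluster| with
    replacement from the cluster and from the background; each replicate's
    statistic is the mean occurrences per promoter.  The reported cluster and
    background means average the two replicate distributions, the fold ratio
    is their quotient, and the p-value is a two-sided two-sample t-test
    between the replicate distributions (bootstrap-t, anti-conservative:
    replicates are resamples, not independent observations).
    """
    if len(cluster) == 0:
        raise ValueError("cluster is empty")
    if len(background) < len(cluster):
        raise ValueError("background must be at least as large as the cluster")
    rng = np.random.default_rng(seed)
    m = len(cluster)
    clu = _occurrence_vector(kmer, cluster, both_strands)
    bkg = _occurrence_vector(kmer, background, both_strands)
    clu_idx = rng.integers(0, clu.size, size=(n_boot, m))
    bkg_idx = rng.integers(0, bkg.size, size=(n_boot, m))
    clu_reps = clu[clu_idx].mean(axis=1)
    bkg_reps = bkg[bkg_idx].mean(axis=1)
    cluster_mean = float(clu_reps.mean())
    background_mean = float(bkg_reps.mean())
    if clu_reps.std() == 0 and bkg_reps.std() == 0:
        t_stat, p_val = 0.0, 1.0
        if cluster_mean != background_mean:
            t_stat, p_val = float("inf"), 0.0
    else:
        t_stat, p_val = ttest_ind(clu_reps, bkg_reps, equal_var=False)
    fold = cluster_mean / background_mean if background_mean > 0 else None
    return EnrichmentRecord(
        kmer=kmer,
        cluster_mean=cluster_mean,
        background_mean=background_mean,
        fold_ratio=fold,
        t_statistic=float(t_stat),
        p_value=float(p_val),
        n_boot=n_boot,
        seed=seed,
    )


def enrichment_screen(
    module_genes: Sequence[str],
    promoters: PromoterSet,
    background: PromoterSet,
    ratio_tiers: Iterable[float] = (2, 3, 4),
    n_boot: int = 1000,
    seed: int = 0,
    candidate_mode: str = "align",
    min_identity: float = 0.75,
    max_evalue: float = 1e-4,
    k: int = 6,
    min_promoter_fraction: float = 0.8,
    both_strands: bool = False,
    align_params: AlignParams | None = None,
) -> list[EnrichmentRecord]:
    """Screen a gene module's promoters for enriched k-mers.

    Candidates come from :func:`shared_kmer_candidates` (``candidate_mode=
    'align'``, the default) or :func:`direct_kmer_candidates` (``'direct'``).
    Each candidate is scored by :func:`bootstrap_enrichment` against the
    background; records carry nested tier flags (a fold-4 k-mer is also in
    tiers 3 and 2) and are sorted by fold ratio descending.
    """
    module_genes = list(module_genes)
    if len(module_genes) < 2:
        raise ValueError("module must contain at least 2 genes")
    cluster = promoters.subset(module_genes)
    if candidate_mode == "align":
        candidates = shared_kmer_candidates(
            cluster, min_identity, max_evalue, k, align_params
        )
    elif candidate_mode == "direct":
        candidates = direct_kmer_candidates(cluster, k, min_promoter_fraction)
    else:
        raise ValueError(f"unknown candidate_mode {candidate_mode!r}")
    tiers = tuple(sorted(ratio_tiers))
    seeds = np.random.SeedSequence(seed).generate_state(max(len(candidates), 1))
    records: list[EnrichmentRecord] = []
    for child_seed, kmer in zip(seeds, candidates):
        rec = bootstrap_enrichment(
            kmer, cluster, background, n_boot, int(child_seed) % (2**31), both_strands
        )
        rec.support = candidates.provenance.get(kmer, 0)
        if rec.fold_ratio is not None:
            rec.tiers = tuple(t for t in tiers if rec.fold_ratio >= t)
        records.append(rec)
    records.sort(
        key=lambda r: (-(r.fold_ratio if r.fold_ratio is not None else float("inf")), r.kmer)
    )
    return records


def precision_eval(
    found: KmerCandidateSet | Iterable[str],
    known: KnownElementList,
    match_rule: str = "substring_either_strand",
) -> tuple[int, int, float | None]:
    """True/false positives and precision of found k-mers against known
    elements.

    Default rule: a found k-mer is a true positive if it is a substring of a
    known element or a known element is a substring of it, on either strand.
    Returns (nTP, nFP, precision); precision is None for an empty found set.
    """
    if len(known.elements) == 0:
        raise ValueError("known element list is empty")
    if match_rule not in ("substring_either_strand", "substring_forward"):
        raise ValueError(f"unknown match_rule {match_rule!r}")
    found_list = sorted(set(found.kmers if isinstance(found, KmerCandidateSet) else found))
    ntp = 0
    for kmer in found_list:
        variants = [kmer]
        if match_rule == "substring_either_strand":
            variants.append(reverse_complement(kmer))
        is_tp = any(
            v in elem or elem in v for v in variants for elem in known.elements
        )
        ntp += 1 if is_tp else 0
    nfp = len(found_list) - ntp
    precision = ntp / (ntp + nfp) if (ntp + nfp) > 0 else None
    return ntp, nfp, precision
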