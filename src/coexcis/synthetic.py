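"""Synthetic data generators: planted co-expression structure, null matrices,
and promoter sets with planted motifs.

These generators define the study conditions every test and benchmark in this
package runs under.  Expression matrices emulate ternary differential-
expression call tables with blocks of co-regulated genes; promoter sets
emulate 1000-bp upstream regions with a motif planted at controlled
per-promoter rates over a uniform-random background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .datasets import PromoterSet, TernaryExpressionMatrix
from .cisreg import homopolymer_filter

_TERNARY = np.array([-1, 0, 1], dtype=np.int8)


@dataclass
class PlantedExpressionTruth:
    """Ground truth for a planted-module expression matrix.

    module_assignments maps gene ID -> module index (0 = background).
    template_patterns maps module index -> ternary condition vector.
    flip_prob is the per-cell probability of corruption to a random *other*
    ternary value; it must stay below 0.5 or the planted structure is
    unrecoverable by design.
    """

    module_assignments: dict[str, int]
    template_patterns: dict[int, np.ndarray]
    flip_prob: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.flip_prob < 0.5:
            raise ValueError("flip_prob must be in [0, 0.5)")
        self.template_patterns = {
            m: np.asarray(v, dtype=np.int8) for m, v in self.template_patterns.items()
        }
        for m, v in self.template_patterns.items():
            if not np.isin(v, _TERNARY).all():
                raise ValueError(f"template for module {m} is not ternary")
        counts: dict[int, int] = {}
        for m in self.module_assignments.values():
            counts[m] = counts.get(m, 0) + 1
        for m, c in counts.items():
            if m != 0 and c < 1:
                raise ValueError("module sizes must be >= 1")

    def modules(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for g, m in self.module_assignments.items():
            out.setdefault(m, []).append(g)
        return out


@dataclass
class PlantedMotifTruth:
    """Ground truth for promoter sets with a planted motif.

    cluster_rate / background_rate are expected planted copies per promoter
    (Poisson means); the background rate applies to both sets as a baseline,
    the cluster rate is the extra signal planted into cluster promoters only.
    """

    motif: str
    cluster_rate: float
    background_rate: float = 0.0

    def __post_init__(self) -> None:
        self.motif = self.motif.upper()
        if self.cluster_rate < 0 or self.background_rate < 0:
            raise ValueError("rates must be >= 0")
        if not homopolymer_filter(self.motif, k=len(self.motif)):
            raise ValueError(f"motif {self.motif} fails the homopolymer filter")


def planted_block_truth(
    n_modules: int,
    module_size: int,
    n_conditions: int,
    flip_prob: float,
    seed: int,
    anticorrelated: bool = False,
    gene_prefix: str = "g",
) -> PlantedExpressionTruth:
    """Convenience constructor: equal-size modules with random ternary templates.

    Genes are named ``{prefix}0001`` onward; module m occupies a contiguous
    block.  With ``anticorrelated`` the second half of each block gets the
    negated template (down- instead of up-regulated genes of one regulon).
    """
    rng = np.random.default_rng(seed)
    assignments: dict[str, int] = {}
    templates: dict[int, np.ndarray] = {}
    gene = 0
    for m in range(1, n_modules + 1):
        # reject near-constant templates: correlation undefined on them
        while True:
            t = rng.choice(_TERNARY, size=n_conditions)
            if len(np.unique(t)) > 1:
                break
        templates[m] = t
        for _ in range(module_size):
            gene += 1
            assignments[f"{gene_prefix}{gene:04d}"] = m
    if anticorrelated:
        for m in range(1, n_modules + 1):
            templates[-m] = -templates[m]
    return PlantedExpressionTruth(assignments, templates, flip_prob)


def synth_expression(
    n_genes: int,
    n_conditions: int,
    truth: PlantedExpressionTruth,
    seed: int,
    background_freqs: Sequence[float] = (0.1, 0.8, 0.1),
) -> TernaryExpressionMatrix:
    """Generate a ternary matrix with planted co-expressed blocks.

    Module genes receive their module template with each cell independently
    flipped to a uniformly chosen *other* ternary value with probability
    ``truth.flip_prob``.  Background genes (not assigned, or assigned module 0)
    get i.i.d. ternary cells with frequencies ``background_freqs`` for
    (-1, 0, +1).  Reproducible given ``seed``.
    """
    assigned = [g for g, m in truth.module_assignments.items() if m != 0]
    if n_genes < len(assigned):
        raise ValueError("n_genes smaller than the number of assigned genes")
    for m, t in truth.template_patterns.items():
        if len(t) != n_conditions:
            raise ValueError(f"template for module {m} has length {len(t)} != {n_conditions}")
    rng = np.random.default_rng(seed)
    freqs = np.asarray(background_freqs, dtype=float)
    freqs = freqs / freqs.sum()

    gene_ids = list(assigned)
    n_bg = n_genes - len(assigned)
    gene_ids += [f"bg{i:04d}" for i in range(1, n_bg + 1)]
    values = np.empty((n_genes, n_conditions), dtype=np.int8)
    for i, g in enumerate(gene_ids):
        m = truth.module_assignments.get(g, 0)
        if m == 0:
            values[i] = rng.choice(_TERNARY, size=n_conditions, p=freqs)
        else:
            row = truth.template_patterns[m].copy()
            flip = rng.random(n_conditions) < truth.flip_prob
            if flip.any():
                # flip to a uniformly random *different* ternary value
                shift = rng.integers(1, 3, size=int(flip.sum()))
                cur = row[flip] + 1  # map {-1,0,1} -> {0,1,2}
                row[flip] = ((cur + shift) % 3) - 1
            values[i] = row
    return TernaryExpressionMatrix(gene_ids, [f"c{j:03d}" for j in range(1, n_conditions + 1)], values)


def randomize_expression(
    m: TernaryExpressionMatrix, seed: int, mode: str = "column"
) -> TernaryExpressionMatrix:
    """Null matrix: randomly reassign expression values over genes.

    Modes
    -----
    column : permute each condition's observed values across genes (default;
        preserves per-condition up/down/no-change counts — the stricter null).
    global : permute the flattened value multiset over all cells.
    iid : draw cells i.i.d. from the matrix-wide empirical ternary frequencies.
    """
    rng = np.random.default_rng(seed)
    values = m.values.copy()
    if mode == "column":
        for j in range(values.shape[1]):
            values[:, j] = rng.permutation(values[:, j])
    elif mode == "global":
        flat = rng.permutation(values.ravel())
        values = flat.reshape(values.shape)
    elif mode == "iid":
        counts = np.array([(m.values == v).sum() for v in (-1, 0, 1)], dtype=float)
        values = rng.choice(_TERNARY, size=values.shape, p=counts / counts.sum())
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TernaryExpressionMatrix(list(m.gene_ids), list(m.condition_ids), values)


def _insert_motifs(
    seq: np.ndarray, motif: str, n_copies: int, rng: np.random.Generator
) -> list[int]:
    """Insert ``n_copies`` of motif at uniform random non-overlapping positions."""
    L, w = len(seq), len(motif)
    if n_copies == 0:
        return []
    if n_copies * w > L:
        raise ValueError(f"requested {n_copies} insertions exceed capacity of length {L}")
    motif_arr = np.frombuffer(motif.encode(), dtype="S1")
    taken: list[tuple[int, int]] = []
    positions: list[int] = []
    attempts = 0
    while len(positions) < n_copies:
        attempts += 1
        if attempts > 1000 * n_copies:
            raise ValueError("could not place motifs without overlap")
        p = int(rng.integers(0, L - w + 1))
        if any(p < e and s < p + w for s, e in taken):
            continue
        taken.append((p, p + w))
        positions.append(p)
        seq[p : p + w] = motif_arr
    return sorted(positions)


def synth_promoters(
    n_cluster: int,
    n_background: int,
    length: int,
    truth: PlantedMotifTruth,
    seed: int,
) -> tuple[PromoterSet, PromoterSet]:
    """Generate (cluster, background) promoter sets with a planted motif.

    Backgrounds are i.i.d. uniform over ACGT.  Every promoter receives a
    Poisson(``background_rate``) baseline number of planted motif copies;
    cluster promoters additionally receive Poisson(``cluster_rate``) copies.
    Copies are placed at uniform random non-overlapping positions.  Planted
    positions are recorded in each set's ``metadata['planted_positions']``.
    """
    if length < len(truth.motif):
        raise ValueError("promoter length shorter than motif")
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")

    def make_set(n: int, rate: float, prefix: str) -> PromoterSet:
        records: dict[str, str] = {}
        planted: dict[str, list[int]] = {}
        for i in range(1, n + 1):
            gene = f"{prefix}{i:04d}"
            seq = rng.choice(bases, size=length)
            n_copies = int(rng.poisson(rate))
            planted[gene] = _insert_motifs(seq, truth.motif, n_copies, rng)
            records[gene] = seq.tobytes().decode()
        ps = PromoterSet(records)
        ps.metadata["planted_positions"] = planted
        ps.metadata["motif"] = truth.motif
        return ps

    cluster = make_set(n_cluster, truth.cluster_rate + truth.background_rate, "clu")
    background = make_set(n_background, truth.background_rate, "bkg")
    return cluster, background
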