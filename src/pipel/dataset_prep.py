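"""Redundancy reduction, benchmark/independent splitting and balanced subsets.

The under-sampling ensemble needs three preparation steps:

1. ``reduce_redundancy`` — greedy incremental clustering at a pairwise
   identity threshold (default 80%), so near-duplicate peptides cannot
   inflate evaluation.  Identity between two sequences is the number of
   matches in the match-maximizing global alignment divided by the
   shorter sequence's length.
2. ``split_dataset`` — stratified random 80/20 benchmark/independent
   split, reproducible from a seed.
3. ``make_balanced_subsets`` — k subsets each pairing *all* minority
   peptides with an equal-size majority draw, with the guarantee that
   every majority peptide appears in at least one subset (a shuffled
   pool that refills once exhausted; no duplicates within a subset).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .io_core import LABEL_NONPIP, LABEL_PIP, Peptide, PeptideDataset, PipelError


class SubsetError(PipelError):
    """Balanced-subset coverage cannot be achieved with the given k."""


@dataclass(frozen=True)
class SplitSpec:
    benchmark_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.benchmark_fraction < 1:
            raise ValueError("benchmark_fraction must be in (0,1)")


@dataclass(frozen=True)
class BalancedSubset:
    subset_id: int
    minority_ids: tuple[str, ...]
    majority_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.majority_ids) != len(self.minority_ids):
            raise ValueError("subset is not 1:1 balanced")
        if len(set(self.majority_ids)) != len(self.majority_ids):
            raise ValueError("duplicate majority ids within a subset")

    def all_ids(self) -> tuple[str, ...]:
        return self.minority_ids + self.majority_ids


@dataclass
class ClusterResult:
    representatives: PeptideDataset
    members: dict[str, list[str]] = field(default_factory=dict)  # rep id -> member ids


def _make_aligner() -> Align.PairwiseAligner:
    # match=1, mismatch=0, gaps=0: the optimal global score equals the
    # maximum number of matched residues over all global alignments.
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = 0.0
    aligner.extend_gap_score = 0.0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Matches in the match-maximizing global alignment / shorter length."""
    if not a or not b:
        return 0.0
    matches = _ALIGNER.score(a, b)
    return matches / min(len(a), len(b))


def reduce_redundancy(
    ds: PeptideDataset, identity_threshold: float = 0.8
) -> tuple[PeptideDataset, ClusterResult]:
    """Greedy incremental clustering; keeps one representative per cluster.

    Sequences are visited in order of decreasing length (ties broken by
    input order); each joins the first retained representative whose
    pairwise identity exceeds the threshold, else founds a new cluster.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0,1]")
    order = sorted(range(len(ds)), key=lambda i: -len(ds[i]))
    reps: list[Peptide] = []
    members: dict[str, list[str]] = {}
    for i in order:
        pep = ds[i]
        for rep in reps:
            if pairwise_identity(pep.sequence, rep.sequence) > identity_threshold:
                members[rep.id].append(pep.id)
                break
        else:
            reps.append(pep)
            members[pep.id] = [pep.id]
    rep_ids = {r.id for r in reps}
    kept = [p for p in ds if p.id in rep_ids]  # preserve input order
    out = PeptideDataset(
        kept,
        ds.provenance
        + [f"reduce_redundancy @{identity_threshold:.2f}: {len(ds)} -> {len(kept)}"],
    )
    return out, ClusterResult(out, members)


def split_dataset(
    ds: PeptideDataset, spec: SplitSpec
) -> tuple[PeptideDataset, PeptideDataset]:
    """Stratified benchmark/independent split, reproducible from the seed."""
    rng = np.random.default_rng(spec.seed)
    bench_ids: list[str] = []
    indep_ids: list[str] = []
    for label in (LABEL_PIP, LABEL_NONPIP):
        ids = [p.id for p in ds if p.label == label]
        if len(ids) < 2:
            raise ValueError(f"class {label} has fewer than 2 members")
        perm = rng.permutation(len(ids))
        n_bench = int(round(spec.benchmark_fraction * len(ids)))
        n_bench = min(max(n_bench, 1), len(ids) - 1)  # both sides non-empty
        bench_ids.extend(ids[i] for i in perm[:n_bench])
        indep_ids.extend(ids[i] for i in perm[n_bench:])
    note = f"split seed={spec.seed} frac={spec.benchmark_fraction}"
    return (
        ds.subset(bench_ids, f"benchmark ({note})"),
        ds.subset(indep_ids, f"independent ({note})"),
    )


def minority_majority(ds: PeptideDataset) -> tuple[str, str]:
    counts = ds.class_counts()
    n_pip = counts.get(LABEL_PIP, 0)
    n_non = counts.get(LABEL_NONPIP, 0)
    if n_pip == 0 or n_non == 0:
        raise ValueError("both classes must be present")
    return (LABEL_PIP, LABEL_NONPIP) if n_pip <= n_non else (LABEL_NONPIP, LABEL_PIP)


def make_balanced_subsets(
    ds: PeptideDataset, k: int = 10, seed: int = 0
) -> list[BalancedSubset]:
    """k balanced 1:1 subsets covering every majority-class peptide.

    Majority ids are drawn from a shuffled pool without replacement across
    subsets; once exhausted the pool refills with a fresh shuffle, skipping
    ids already drawn into the current subset, so coverage is guaranteed
    and no subset contains duplicates.
    """
    min_label, maj_label = minority_majority(ds)
    minority = tuple(p.id for p in ds if p.label == min_label)
    majority = [p.id for p in ds if p.label == maj_label]
    m, M = len(minority), len(majority)
    if k * m < M:
        import math
        raise SubsetError(
            f"coverage impossible: k*minority = {k * m} < majority = {M}; "
            f"need k >= {math.ceil(M / m)}"
        )
    rng = np.random.default_rng(seed)
    pool: list[str] = [majority[i] for i in rng.permutation(M)]
    subsets: list[BalancedSubset] = []
    for sid in range(1, k + 1):
        drawn: list[str] = []
        while len(drawn) < m:
            if not pool:
                pool = [majority[i] for i in rng.permutation(M)]
            cand = pool.pop()
            if cand in drawn:
                continue
            drawn.append(cand)
        subsets.append(BalancedSubset(sid, minority, tuple(drawn)))
    return subsets


def subsets_to_tsv(subsets: list[BalancedSubset], path: str) -> None:
    """Export subset assignments: peptide id, comma-joined subset ids."""
    assign: dict[str, list[int]] = {}
    for s in subsets:
        for pid in s.all_ids():
            assign.setdefault(pid, []).append(s.subset_id)
    with open(path, "w") as fh:
        for pid, sids in assign.items():
            fh.write(f"{pid}\t{','.join(map(str, sids))}\n")
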