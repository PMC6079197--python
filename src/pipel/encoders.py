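"""Composition-based peptide feature encodings and min-max normalization.

Five schemes turn a peptide into a fixed-length numeric vector:

* **AAC** (20): per-residue frequencies, count(i)/L.
* **DPC** (400): overlapping-dipeptide frequencies, count(ij)/(L-1), in
  lexicographic dipeptide order.
* **CTD** (147): for each of 7 physicochemical attributes whose 3-class
  residue partition is vendored in ``data/ctd_groups.tsv``, 3 composition
  percentages, 3 transition percentages and 5x3 distribution percentiles
  (21 per attribute, attribute-major).
* **AAI** (20 default / 160 full): amino-acid-composition weighting of 8
  high-quality AAindex scales, each scale min-max scaled to [0,1] over the
  20 residues; the default averages the 8 scales into 20 features.
* **PCP** (9): whole-sequence physicochemical quantities (hydropathy and
  charge fractions, turn propensity, absolute net charge per residue,
  molecular weight, aliphatic index).

The HYBRID scheme concatenates AAC|DPC|CTD|AAI(20)|PCP (596 features).
All encoders are pure functions of the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

from .io_core import CANONICAL_ALPHABET, Peptide, PipelError

WATER_MASS = 18.01528

SCHEME_AAC = "AAC"
SCHEME_DPC = "DPC"
SCHEME_CTD = "CTD"
SCHEME_AAI = "AAI"
SCHEME_PCP = "PCP"
SCHEME_HYBRID = "HYBRID"
ALL_SCHEMES = (SCHEME_AAC, SCHEME_DPC, SCHEME_CTD, SCHEME_PCP, SCHEME_AAI)

_AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_ALPHABET)}
DIPEPTIDES = tuple(a + b for a in CANONICAL_ALPHABET for b in CANONICAL_ALPHABET)
_DP_INDEX = {dp: i for i, dp in enumerate(DIPEPTIDES)}


class EncodingError(PipelError):
    """Sequence fails an encoder precondition (e.g. L<2 for DPC)."""


@dataclass(frozen=True)
class FeatureVector:
    scheme: str
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.names) != len(self.values):
            raise ValueError("names/values length mismatch")

    def __len__(self) -> int:
        return len(self.values)


# --------------------------------------------------------------------------
# vendored constant tables
# --------------------------------------------------------------------------

def _data_lines(name: str) -> list[str]:
    text = resources.files("pipel.data").joinpath(name).read_text()
    return [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


def load_ctd_groups() -> dict[str, dict[str, str]]:
    """attribute -> {group_name: residue_string}; 3 disjoint groups covering
    the full alphabet for each of the 7 attributes."""
    tables: dict[str, dict[str, str]] = {}
    for ln in _data_lines("ctd_groups.tsv"):
        parts = ln.split("\t")
        attr, pairs = parts[0], parts[1:]
        groups = {pairs[i]: pairs[i + 1] for i in range(0, 6, 2)}
        merged = "".join(groups.values())
        if sorted(merged) != sorted(CANONICAL_ALPHABET):
            raise ValueError(f"CTD attribute {attr}: groups are not a partition")
        tables[attr] = groups
    if len(tables) != 7:
        raise ValueError("expected 7 CTD attributes")
    return tables


def load_aaindex() -> tuple[tuple[str, ...], np.ndarray]:
    """The 8 high-quality AAindex scales, each min-max scaled to [0,1]
    over the 20 residues.  Returns (index ids, 8x20 matrix in alphabet
    order)."""
    lines = _data_lines("aaindex8.tsv")
    header = lines[0].split("\t")
    order = header[1:]
    ids, rows = [], []
    for ln in lines[1:]:
        parts = ln.split("\t")
        ids.append(parts[0])
        vals = dict(zip(order, map(float, parts[1:])))
        rows.append([vals[aa] for aa in CANONICAL_ALPHABET])
    mat = np.asarray(rows, dtype=float)
    lo = mat.min(axis=1, keepdims=True)
    hi = mat.max(axis=1, keepdims=True)
    return tuple(ids), (mat - lo) / (hi - lo)


def load_residue_masses() -> dict[str, float]:
    masses: dict[str, float] = {}
    for ln in _data_lines("residue_masses.tsv"):
        aa, m = ln.split("\t")
        if aa == "residue":
            continue
        masses[aa] = float(m)
    return masses


CTD_GROUPS = load_ctd_groups()
CTD_ATTRIBUTES = tuple(CTD_GROUPS)
AAINDEX_IDS, AAINDEX_SCALED = load_aaindex()
RESIDUE_MASSES = load_residue_masses()


# --------------------------------------------------------------------------
# AAC / DPC
# --------------------------------------------------------------------------

def encode_aac(p: Peptide) -> FeatureVector:
    """Amino-acid composition: count(i)/L for the 20 residues; sums to 1."""
    counts = np.zeros(20)
    for aa in p.sequence:
        counts[_AA_INDEX[aa]] += 1
    return FeatureVector(SCHEME_AAC, tuple(f"AAC_{a}" for a in CANONICAL_ALPHABET),
                         counts / len(p))


def encode_dpc(p: Peptide) -> FeatureVector:
    """Dipeptide composition: overlapping adjacent-pair counts / (L-1)."""
    if len(p) < 2:
        raise EncodingError(f"peptide {p.id!r}: DPC undefined for length < 2")
    counts = np.zeros(400)
    seq = p.sequence
    for i in range(len(seq) - 1):
        counts[_DP_INDEX[seq[i:i + 2]]] += 1
    return FeatureVector(SCHEME_DPC, tuple(f"DPC_{d}" for d in DIPEPTIDES),
                         counts / (len(seq) - 1))


# --------------------------------------------------------------------------
# CTD
# --------------------------------------------------------------------------

_DISTRIBUTION_QUANTILES = (0.0, 0.25, 0.50, 0.75, 1.0)


def _quantile_occurrence(n_occ: int, q: float) -> int:
    """1-based occurrence index of the q-quantile occurrence: the first for
    q=0, the n-th for q=1, otherwise nearest-with-ties-up of q*n."""
    if q == 0.0:
        return 1
    return max(1, int(np.floor(q * n_occ + 0.5)))


def encode_ctd(p: Peptide, tables: dict[str, dict[str, str]] | None = None) -> FeatureVector:
    """147 composition-transition-distribution descriptors (21 x 7).

    Per attribute: C = 3 group percentages (sum 100); T = percentage of
    adjacent positions whose residues belong to distinct groups, counted
    in either order over the L-1 pairs; D = for each group, sequence
    positions (as % of L) of the first, 25/50/75-percentile and last
    occurrence, zeros for an absent group.
    """
    tables = tables if tables is not None else CTD_GROUPS
    seq = p.sequence
    L = len(seq)
    names: list[str] = []
    values: list[float] = []
    for attr, groups in tables.items():
        gnames = list(groups)
        membership = {}
        for gi, res in enumerate(groups.values()):
            for aa in res:
                membership[aa] = gi
        codes = [membership[aa] for aa in seq]
        # composition
        for gi, gn in enumerate(gnames):
            names.append(f"CTD_{attr}_C_{gn}")
            values.append(100.0 * codes.count(gi) / L)
        # transitions between distinct group pairs (unordered)
        pair_counts = {(0, 1): 0, (0, 2): 0, (1, 2): 0}
        for a, b in zip(codes, codes[1:]):
            if a != b:
                pair_counts[(min(a, b), max(a, b))] += 1
        for (a, b), c in pair_counts.items():
            names.append(f"CTD_{attr}_T_{gnames[a]}.{gnames[b]}")
            values.append(100.0 * c / (L - 1) if L > 1 else 0.0)
        # distribution
        for gi, gn in enumerate(gnames):
            positions = [i + 1 for i, c in enumerate(codes) if c == gi]
            for q in _DISTRIBUTION_QUANTILES:
                names.append(f"CTD_{attr}_D_{gn}_{int(q * 100)}")
                if not positions:
                    values.append(0.0)
                else:
                    pos = positions[_quantile_occurrence(len(positions), q) - 1]
                    values.append(100.0 * pos / L)
    return FeatureVector(SCHEME_CTD, tuple(names), np.asarray(values))


# --------------------------------------------------------------------------
# AAI
# --------------------------------------------------------------------------

def encode_aai(p: Peptide, full: bool = False) -> FeatureVector:
    """AAindex-weighted composition.

    full=True: for each of the 8 scaled indices j and residue i,
    AAC(i) * index_j(i) -> 160 features (index-major).  Default: the
    8-index mean per residue -> 20 features.
    """
    aac = encode_aac(p).values
    if full:
        mat = AAINDEX_SCALED * aac[np.newaxis, :]
        names = tuple(
            f"AAI_{idx}_{aa}" for idx in AAINDEX_IDS for aa in CANONICAL_ALPHABET
        )
        return FeatureVector(SCHEME_AAI, names, mat.ravel())
    mean_idx = AAINDEX_SCALED.mean(axis=0)
    return FeatureVector(
        SCHEME_AAI,
        tuple(f"AAI_mean_{aa}" for aa in CANONICAL_ALPHABET),
        aac * mean_idx,
    )


# --------------------------------------------------------------------------
# PCP
# --------------------------------------------------------------------------

_PCP_GROUPS = {
    "hydrophobic": "FIWLVMYCA",
    "hydrophilic": "RKNDEP",
    "neutral": "THGSQ",
    "positive": "KHR",
    "negative": "DE",
    "turn": "NGPS",
}
PCP_NAMES = (
    "PCP_hydrophobic_frac", "PCP_hydrophilic_frac", "PCP_neutral_frac",
    "PCP_positive_frac", "PCP_negative_frac", "PCP_turn_frac",
    "PCP_abs_charge_per_residue", "PCP_molecular_weight", "PCP_aliphatic_index",
)


def encode_pcp(p: Peptide) -> FeatureVector:
    """Nine sequence-level physicochemical quantities.

    Fractions of hydrophobic/hydrophilic/neutral and charged residues,
    turn-forming fraction (N+G+P+S)/n, absolute net charge per residue
    |(R+K-D-E)/n - 0.03|, average molecular weight (residue masses plus
    one water) and the aliphatic index (A + 2.9V + 3.9I + 3.9L)/n, with
    letters denoting residue counts.
    """
    seq = p.sequence
    n = len(seq)
    cnt = {aa: seq.count(aa) for aa in CANONICAL_ALPHABET}
    fracs = [sum(cnt[aa] for aa in res) / n for res in _PCP_GROUPS.values()]
    abs_charge = abs((cnt["R"] + cnt["K"] - cnt["D"] - cnt["E"]) / n - 0.03)
    mw = sum(cnt[aa] * RESIDUE_MASSES[aa] for aa in CANONICAL_ALPHABET) + WATER_MASS
    aliphatic = (cnt["A"] + 2.9 * cnt["V"] + 3.9 * cnt["I"] + 3.9 * cnt["L"]) / n
    return FeatureVector(SCHEME_PCP, PCP_NAMES,
                         np.asarray(fracs + [abs_charge, mw, aliphatic]))


# --------------------------------------------------------------------------
# hybrid + matrix helpers
# --------------------------------------------------------------------------

def encode_hybrid(p: Peptide) -> FeatureVector:
    """AAC | DPC | CTD | AAI(20) | PCP concatenation, 596 features."""
    parts = [encode_aac(p), encode_dpc(p), encode_ctd(p), encode_aai(p), encode_pcp(p)]
    names = tuple(n for fv in parts for n in fv.names)
    values = np.concatenate([fv.values for fv in parts])
    return FeatureVector(SCHEME_HYBRID, names, values)


_ENCODERS = {
    SCHEME_AAC: encode_aac,
    SCHEME_DPC: encode_dpc,
    SCHEME_CTD: encode_ctd,
    SCHEME_AAI: encode_aai,
    SCHEME_PCP: encode_pcp,
    SCHEME_HYBRID: encode_hybrid,
}


def encode(p: Peptide, scheme: str) -> FeatureVector:
    try:
        enc = _ENCODERS[scheme]
    except KeyError:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {list(_ENCODERS)}")
    return enc(p)


def encode_matrix(peptides: Iterable[Peptide], scheme: str) -> tuple[np.ndarray, tuple[str, ...]]:
    """Encode peptides into an (n, p) matrix; returns (matrix, feature names)."""
    vectors = [encode(p, scheme) for p in peptides]
    if not vectors:
        raise ValueError("no peptides to encode")
    return np.vstack([fv.values for fv in vectors]), vectors[0].names


# --------------------------------------------------------------------------
# min-max normalization (fit on training data only)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizationStats:
    scheme: str
    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        if self.mins.shape != self.maxs.shape:
            raise ValueError("min/max shape mismatch")
        if np.any(self.mins > self.maxs):
            raise ValueError("per-feature min exceeds max")


def fit_normalizer(matrix: np.ndarray, scheme: str = "") -> NormalizationStats:
    """Per-feature min/max from a training matrix."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0:
        raise ValueError("cannot fit normalizer on an empty matrix")
    return NormalizationStats(scheme, matrix.min(axis=0), matrix.max(axis=0))


def apply_normalizer(stats: NormalizationStats, matrix: np.ndarray) -> np.ndarray:
    """(x - min)/(max - min), constant features -> 0, clipped to [0,1]."""
    matrix = np.asarray(matrix, dtype=float)
    span = stats.maxs - stats.mins
    out = np.zeros_like(matrix)
    nonconst = span > 0
    out[:, nonconst] = (matrix[:, nonconst] - stats.mins[nonconst]) / span[nonconst]
    return np.clip(out, 0.0, 1.0)


def matrix_to_tsv(matrix: np.ndarray, names: Sequence[str], ids: Sequence[str],
                  path: str) -> None:
    """Export a feature matrix as TSV: header = feature names, rows = ids."""
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(names) + "\n")
        for pid, row in zip(ids, matrix):
            fh.write(pid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
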