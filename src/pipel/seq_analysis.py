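"""Compositional and positional contrasts between positive and negative sets.

Two complementary views of what distinguishes the classes:

* ``contrast_composition`` — per-residue (AAC) or per-dipeptide (DPC)
  Welch's t-tests on per-peptide composition values, flagging features
  whose mean composition differs between classes (default alpha 0.01).
* ``contrast_positions`` — two-sample-logo-style position-wise tests on
  residue occurrence indicators over the first 10 positions from each
  terminus (default alpha 0.05), flagging enriched and depleted
  (residue, position) pairs.

Peptides shorter than the positional window contribute only the
positions they actually have; no padding residues are fabricated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .encoders import encode_matrix
from .io_core import CANONICAL_ALPHABET, LABEL_NONPIP, LABEL_PIP, PeptideDataset

DIRECTION_ENRICHED = "enriched"
DIRECTION_DEPLETED = "depleted"


@dataclass(frozen=True)
class CompositionContrast:
    feature: str
    mean_pos: float
    mean_neg: float
    p_value: float
    enriched_in: str  # PIP / NONPIP / none

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0,1]")


@dataclass(frozen=True)
class PositionalContrast:
    terminus: str  # N or C
    position: int  # 1-based, counting inward from the terminus
    residue: str
    direction: str  # enriched / depleted (in the positive set)
    p_value: float
    freq_pos: float
    freq_neg: float


def _welch(a: np.ndarray, b: np.ndarray) -> float:
    """Welch's two-sided t-test p-value; identical degenerate samples
    (zero variance, equal means) count as indistinguishable (p=1)."""
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    return float(_stats.ttest_ind(a, b, equal_var=False).pvalue)


def contrast_composition(
    pos: PeptideDataset,
    neg: PeptideDataset,
    scheme: str = "AAC",
    alpha: float = 0.01,
) -> list[CompositionContrast]:
    """Per-feature Welch's t-test of composition between the two sets.

    Returns one record per feature; ``enriched_in`` names the class with
    the larger mean for features with p <= alpha, otherwise "none".
    """
    if scheme not in ("AAC", "DPC"):
        raise ValueError("composition contrast supports AAC or DPC")
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("each set needs at least 2 peptides")
    Xp, names = encode_matrix(pos.peptides, scheme)
    Xn, _ = encode_matrix(neg.peptides, scheme)
    out: list[CompositionContrast] = []
    for j, name in enumerate(names):
        p_val = _welch(Xp[:, j], Xn[:, j])
        mp, mn = float(Xp[:, j].mean()), float(Xn[:, j].mean())
        if p_val <= alpha and mp != mn:
            enriched = LABEL_PIP if mp > mn else LABEL_NONPIP
        else:
            enriched = "none"
        out.append(CompositionContrast(name.split("_", 1)[1], mp, mn, p_val, enriched))
    return out


def _occurrence_indicators(ds: PeptideDataset, terminus: str, position: int,
                           residue: str) -> np.ndarray:
    """0/1 indicator per peptide of `residue` at the given terminal position,
    restricted to peptides long enough to have that position."""
    vals = []
    for p in ds:
        if len(p) < position:
            continue
        aa = p.sequence[position - 1] if terminus == "N" else p.sequence[-position]
        vals.append(1.0 if aa == residue else 0.0)
    return np.asarray(vals)


def contrast_positions(
    pos: PeptideDataset,
    neg: PeptideDataset,
    window: int = 10,
    alpha: float = 0.05,
) -> list[PositionalContrast]:
    """Two-sample-logo-style positional contrast over both termini.

    For each terminus (N counting forward from the first residue, C
    counting backward from the last), position 1..window and residue, a
    two-sample t-test on occurrence indicators flags significant
    enrichment or depletion in the positive set.  Only flagged records
    are returned.
    """
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both sets must be non-empty")
    out: list[PositionalContrast] = []
    for terminus in ("N", "C"):
        for position in range(1, window + 1):
            for residue in CANONICAL_ALPHABET:
                a = _occurrence_indicators(pos, terminus, position, residue)
                b = _occurrence_indicators(neg, terminus, position, residue)
                if len(a) < 2 or len(b) < 2:
                    continue
                p_val = _welch(a, b)
                if p_val < alpha and a.mean() != b.mean():
                    direction = (DIRECTION_ENRICHED if a.mean() > b.mean()
                                 else DIRECTION_DEPLETED)
                    out.append(PositionalContrast(
                        terminus, position, residue, direction, p_val,
                        float(a.mean()), float(b.mean())))
    return out


def composition_contrast_to_tsv(contrasts: list[CompositionContrast], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("feature\tmean_pos\tmean_neg\tp_value\tenriched_in\n")
        for c in contrasts:
            fh.write(f"{c.feature}\t{c.mean_pos:.6g}\t{c.mean_neg:.6g}"
                     f"\t{c.p_value:.4g}\t{c.enriched_in}\n")


def logo_matrix(pos: PeptideDataset, neg: PeptideDataset, terminus: str,
                window: int = 10) -> tuple[np.ndarray, list[str]]:
    """Position x residue frequency-difference matrix (positive minus
    negative), suitable for two-sample-logo rendering."""
    mat = np.zeros((window, 20))
    for pi in range(1, window + 1):
        for ri, residue in enumerate(CANONICAL_ALPHABET):
            a = _occurrence_indicators(pos, terminus, pi, residue)
            b = _occurrence_indicators(neg, terminus, pi, residue)
            mat[pi - 1, ri] = (a.mean() if len(a) else 0.0) - (b.mean() if len(b) else 0.0)
    return mat, list(CANONICAL_ALPHABET)


def logo_matrix_to_tsv(mat: np.ndarray, residues: list[str], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("position\t" + "\t".join(residues) + "\n")
        for i, row in enumerate(mat, 1):
            fh.write(str(i) + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
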