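"""Cross-structure residue pairing and profile comparison.

Two homologous structures rarely share a residue count (cathepsin G has
224 residues, neutrophil elastase 240), so per-residue profiles cannot be
compared index by index. A gapped Needleman–Wunsch global alignment of
the two sequences (Bio.Align behind this surface) pairs residues; only
aligned pairs are compared and gap columns are reported empty. The
aligned column count exceeds both sequence lengths when gaps open on
either side.

Profiles must be normalized with the same method before comparison —
raw values from different network types carry different units and a raw
comparison is refused.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .paths import ResidueProfile

_AA = set("ACDEFGHIKLMNPQRSTVWYXBZJUO")


@dataclass
class AlignmentMap:
    """Residue pairing from a global alignment.

    ``pairs`` lists (ordinal in A, ordinal in B), strictly increasing on
    both sides; ``columns`` gives per aligned column the two ordinals,
    with None marking a gap on that side. ``n_columns`` includes gap
    columns, so it is ≥ max(len A, len B).
    """

    n_columns: int
    pairs: list[tuple[int, int]]
    columns: list[tuple[int | None, int | None]]
    aligned_a: str = ""
    aligned_b: str = ""
    score: float = 0.0

    def __post_init__(self) -> None:
        for (a0, b0), (a1, b1) in zip(self.pairs, self.pairs[1:]):
            if a1 <= a0 or b1 <= b0:
                raise ValidationError("alignment pairs must strictly increase")

    def to_fasta(self, path: str | Path, id_a: str = "A", id_b: str = "B") -> None:
        Path(path).write_text(
            f">{id_a}\n{self.aligned_a}\n>{id_b}\n{self.aligned_b}\n"
        )


def global_align(
    seq_a: str,
    seq_b: str,
    sub_matrix: str | None = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    match: float = 1.0,
    mismatch: float = -1.0,
) -> AlignmentMap:
    """Needleman–Wunsch global alignment with affine gap penalties.

    ``sub_matrix`` names a Bio.Align substitution matrix (default
    BLOSUM62); pass None to score with ``match``/``mismatch`` instead.
    ``gap_open``/``gap_extend`` are penalties (positive numbers); use
    ``gap_open == gap_extend`` for linear gap costs. The traceback is
    deterministic: of the co-optimal alignments the first in Bio.Align's
    fixed enumeration order is returned.
    """
    if not seq_a or not seq_b:
        raise ValidationError("sequences must be nonempty")
    for name, seq in (("A", seq_a), ("B", seq_b)):
        bad = set(seq.upper()) - _AA
        if bad:
            raise ValidationError(f"invalid residue characters in sequence {name}: {sorted(bad)}")
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if sub_matrix is not None:
        from Bio.Align import substitution_matrices

        aligner.substitution_matrix = substitution_matrices.load(sub_matrix)
    else:
        aligner.match_score = match
        aligner.mismatch_score = mismatch
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)

    alignment = aligner.align(seq_a.upper(), seq_b.upper())[0]
    text_a, text_b = str(alignment[0]), str(alignment[1])
    columns: list[tuple[int | None, int | None]] = []
    pairs: list[tuple[int, int]] = []
    ia = ib = 0
    for ca, cb in zip(text_a, text_b):
        pos_a = ia if ca != "-" else None
        pos_b = ib if cb != "-" else None
        columns.append((pos_a, pos_b))
        if pos_a is not None and pos_b is not None:
            pairs.append((pos_a, pos_b))
        ia += ca != "-"
        ib += cb != "-"
    return AlignmentMap(
        n_columns=len(columns),
        pairs=pairs,
        columns=columns,
        aligned_a=text_a,
        aligned_b=text_b,
        score=float(alignment.score),
    )


@dataclass
class AlignedComparison:
    """Per-column |Δ normalized profile| between two aligned structures.

    ``differences[k]`` is NaN for gap columns ("residues without a
    partner are ignored"); ``mean_abs_difference`` averages over exactly
    the paired columns.
    """

    differences: np.ndarray
    columns: list[tuple[int | None, int | None]]
    labels_a: list[str | None]
    labels_b: list[str | None]
    mean_abs_difference: float

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "column_index": np.arange(self.n_columns),
                "labelA": ["" if x is None else x for x in self.labels_a],
                "labelB": ["" if x is None else x for x in self.labels_b],
                "diff": self.differences,
            }
        ).to_csv(path, index=False)


def compare_profiles(
    prof_a: ResidueProfile, prof_b: ResidueProfile, amap: AlignmentMap
) -> AlignedComparison:
    """Absolute per-pair difference of two normalized profiles.

    Both profiles must come from networks with the same cost semantics
    and be normalized with the same method; symmetric in (A, B).
    """
    if prof_a.normalized is None or prof_b.normalized is None:
        raise ValidationError(
            "profiles must be normalized before comparison (units differ otherwise)"
        )
    if prof_a.normalized != prof_b.normalized:
        raise ValidationError(
            f"profiles normalized differently: {prof_a.normalized} vs {prof_b.normalized}"
        )
    if prof_a.semantics != prof_b.semantics:
        raise ValidationError(
            f"cannot compare profiles from different network types: "
            f"{prof_a.semantics} vs {prof_b.semantics}"
        )
    if amap.pairs:
        max_a = max(a for a, _ in amap.pairs)
        max_b = max(b for _, b in amap.pairs)
        if max_a >= prof_a.n_residues or max_b >= prof_b.n_residues:
            raise ValidationError("alignment refers to residues beyond the profiles")

    diffs = np.full(amap.n_columns, np.nan)
    labels_a: list[str | None] = []
    labels_b: list[str | None] = []
    for k, (pa, pb) in enumerate(amap.columns):
        labels_a.append(prof_a.labels[pa] if pa is not None else None)
        labels_b.append(prof_b.labels[pb] if pb is not None else None)
        if pa is not None and pb is not None:
            diffs[k] = abs(prof_a.values[pa] - prof_b.values[pb])
    paired = diffs[~np.isnan(diffs)]
    mean = float(paired.mean()) if paired.size else 0.0
    return AlignedComparison(
        differences=diffs,
        columns=list(amap.columns),
        labels_a=labels_a,
        labels_b=labels_b,
        mean_abs_difference=mean,
    )
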