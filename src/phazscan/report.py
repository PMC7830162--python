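"""Conserved-feature report rendering and pairwise candidate similarity.

The feature report lays out, for each passing candidate, sequence windows
around the four conserved features (oxyanion pocket, lipase box, catalytic
Asp, catalytic His) — the textual equivalent of a colour-coded alignment
figure. Pairwise similarity between candidate proteins is the percentage of
positive-scoring columns of a local affine-gap alignment (BLOSUM62, gap open
11, extend 1 by default), with gap columns counted in the denominator — the
common BLASTP "positives" notion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import ProteinRecord
from .screen import CandidateReport

FEATURE_ORDER = ("oxyanion", "lipase_box", "asp", "his")


class ReportError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureBlock:
    protein_id: str
    feature_role: str  # oxyanion | lipase_box | asp | his
    window: str
    window_start: int  # 1-based
    highlight_offsets: tuple[int, ...]  # 0-based offsets within window


@dataclass(frozen=True)
class SimilarityResult:
    id_a: str
    id_b: str
    alignment_length: int
    pct_identity: float
    pct_similarity: float
    score: float

    def __post_init__(self) -> None:
        if self.pct_similarity < self.pct_identity:
            raise ReportError("pct_similarity must be >= pct_identity")


@dataclass(frozen=True)
class AlignParams:
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0


def _window(seq: str, start: int, end: int, flank: int) -> tuple[str, int, tuple[int, ...]]:
    ws = max(1, start - flank)
    we = min(len(seq), end + flank)
    window = seq[ws - 1 : we]
    offsets = tuple(range(start - ws, end - ws + 1))
    return window, ws, offsets


def extract_feature_blocks(
    report: CandidateReport, protein: ProteinRecord, flank: int = 5
) -> list[FeatureBlock]:
    """Windows around the four conserved features of a passing candidate.

    Windows are clipped at the sequence termini with the window start
    adjusted; blocks come in the fixed order oxyanion, lipase box, Asp, His.
    """
    if not report.passes:
        raise ReportError(f"{report.protein_id}: feature blocks require a passing report")
    assert report.oxyanion and report.lipase_box and report.triad
    seq = protein.sequence
    spans = {
        "oxyanion": (report.oxyanion.start, report.oxyanion.end),
        "lipase_box": (report.lipase_box.start, report.lipase_box.end),
        "asp": (report.triad.asp_pos, report.triad.asp_pos),
        "his": (report.triad.his_pos, report.triad.his_pos),
    }
    blocks = []
    for role in FEATURE_ORDER:
        s, e = spans[role]
        window, ws, offsets = _window(seq, s, e, flank)
        blocks.append(
            FeatureBlock(
                protein_id=report.protein_id,
                feature_role=role,
                window=window,
                window_start=ws,
                highlight_offsets=offsets,
            )
        )
    return blocks


def _render_cell(block: FeatureBlock) -> str:
    lo, hi = block.highlight_offsets[0], block.highlight_offsets[-1] + 1
    w = block.window
    return f"{w[:lo]}[{w[lo:hi]}]{w[hi:]} ({block.window_start + lo})"


def render_feature_table(blocks_by_protein: Sequence[Sequence[FeatureBlock]]) -> str:
    """Plain-text table: one row per protein, one column per feature role.

    Each cell shows the window with the feature span bracketed and the
    feature's 1-based start position. Input order is preserved.
    """
    header = ["protein_id", *FEATURE_ORDER]
    rows = [header]
    for blocks in blocks_by_protein:
        by_role = {b.feature_role: b for b in blocks}
        pid = blocks[0].protein_id if blocks else ""
        rows.append([pid] + [_render_cell(by_role[r]) for r in FEATURE_ORDER])
    widths = [max(len(r[i]) for r in rows) for i in range(len(header))]
    lines = [
        "  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip() for row in rows
    ]
    return "\n".join(lines) + "\n"


def write_feature_table_tsv(
    blocks_by_protein: Sequence[Sequence[FeatureBlock]], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(["protein_id", *FEATURE_ORDER]) + "\n")
        for blocks in blocks_by_protein:
            by_role = {b.feature_role: b for b in blocks}
            pid = blocks[0].protein_id if blocks else ""
            fh.write(
                "\t".join([pid] + [_render_cell(by_role[r]) for r in FEATURE_ORDER]) + "\n"
            )


# ---------------------------------------------------------------------------
# Pairwise similarity


def _aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    # Convention: a gap of length k costs open + (k-1)*extend.
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def pairwise_similarity(
    a: ProteinRecord, b: ProteinRecord, params: Optional[AlignParams] = None
) -> SimilarityResult:
    """Local-alignment percent identity and percent similarity of two proteins.

    Similarity counts alignment columns whose substitution score is positive;
    identity counts identical columns; gap columns count in the denominator of
    both. Symmetric in its arguments.
    """
    if not a.sequence or not b.sequence:
        raise ReportError("pairwise_similarity requires non-empty sequences")
    params = params or AlignParams()
    # Canonical input order makes tie-broken optimal alignments symmetric.
    first, second = sorted((a, b), key=lambda r: (r.sequence, r.id))
    aligner = _aligner(params)
    matrix = aligner.substitution_matrix
    alignments = aligner.align(first.sequence, second.sequence)
    if len(alignments) == 0:  # no positive-scoring local alignment at all
        return SimilarityResult(
            id_a=a.id, id_b=b.id, alignment_length=0,
            pct_identity=0.0, pct_similarity=0.0, score=0.0,
        )
    aln = alignments[0]
    sa, sb = str(aln[0]), str(aln[1])
    ncols = len(sa)
    ident = 0
    positive = 0
    for x, y in zip(sa, sb):
        if x == "-" or y == "-":
            continue
        if x == y:
            ident += 1
        # identical-residue columns always count as similar, even for letters
        # the matrix scores non-positively against themselves (e.g. X)
        if x == y or matrix[x, y] > 0:
            positive += 1
    return SimilarityResult(
        id_a=a.id,
        id_b=b.id,
        alignment_length=ncols,
        pct_identity=100.0 * ident / ncols,
        pct_similarity=100.0 * positive / ncols,
        score=float(aln.score),
    )


def write_similarity_results(
    results: Sequence[SimilarityResult], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id_a\tid_b\talignment_length\tpct_identity\tpct_similarity\tscore\n")
        for r in results:
            fh.write(
                f"{r.id_a}\t{r.id_b}\t{r.alignment_length}\t"
                f"{r.pct_identity:.1f}\t{r.pct_similarity:.1f}\t{r.score:g}\n"
            )
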