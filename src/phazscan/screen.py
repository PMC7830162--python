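"""The refined extracellular-depolymerase screen.

A protein is a candidate extracellular PHA depolymerase when it (1) carries a
predicted signal peptide, (2) carries an alpha/beta-hydrolase fold domain
annotation, and (3) contains the conserved features in canonical order:
oxyanion pocket, then the lipase box with the catalytic serine, then the
remaining triad residues aspartate and histidine. Surviving candidates are
classified by their lipase-box flavour (depolymerase-like AHSXG variants vs
the triacylglycerol-lipase-like GHSXH box vs the generic GXSXG).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio.SeqUtils.ProtParamData import kd as _KYTE_DOOLITTLE

from .io_formats import DomainHit, ProteinRecord, SignalPeptideCall
from .motif_engine import (
    CatalyticTriad,
    MotifMatch,
    MotifPattern,
    ROLE_LIPASE_BOX,
    ROLE_OXYANION,
    default_patterns,
    evaluate_order,
    find_triads,
    scan,
)

#: Fold signatures indicating membership of the alpha/beta hydrolase
#: superfamily. Config data, not hard-coded truth: verify against current
#: InterPro before using on real annotations.
DEFAULT_FOLD_SIGNATURES = frozenset({"SSF53474", "G3DSA:3.40.50.1820"})
DEFAULT_FOLD_KEYWORDS = ("alpha/beta hydrolase", "alpha/beta-hydrolase")

CLASS_AHSXG = "AHSXG-type"
CLASS_GHSXH = "GHSXH-type"
CLASS_GXSXG = "GXSXG-type"
CLASS_OTHER = "other"
CLASS_NONE = "none"

#: Lipase-box pattern names mapping to the depolymerase-like class.
_AHSXG_FAMILY = frozenset({"AHSXG", "AHSMGV", "AITSSTG"})


class ScreenError(ValueError):
    pass


@dataclass(frozen=True)
class ScreenConfig:
    fold_signature_ids: frozenset = DEFAULT_FOLD_SIGNATURES
    fold_description_keywords: tuple[str, ...] = DEFAULT_FOLD_KEYWORDS
    pattern_library: tuple[MotifPattern, ...] = ()
    search_region: str = "mature"  # or "full"
    sp_fallback_enabled: bool = False

    def __post_init__(self) -> None:
        if self.search_region not in ("mature", "full"):
            raise ScreenError(f"search_region must be 'mature' or 'full', got {self.search_region!r}")
        lib = self.pattern_library or tuple(default_patterns())
        object.__setattr__(self, "pattern_library", tuple(lib))
        roles = {p.role for p in self.pattern_library}
        if not {ROLE_OXYANION, ROLE_LIPASE_BOX} <= roles:
            raise ScreenError("pattern library needs >=1 oxyanion and >=1 lipase_box pattern")

    @property
    def oxyanion_patterns(self) -> list[MotifPattern]:
        return [p for p in self.pattern_library if p.role == ROLE_OXYANION]

    @property
    def lipase_patterns(self) -> list[MotifPattern]:
        return [p for p in self.pattern_library if p.role == ROLE_LIPASE_BOX]


@dataclass(frozen=True)
class CandidateReport:
    """Per-protein screening verdict with the located features."""

    protein_id: str
    secreted: bool
    has_fold: bool
    oxyanion: Optional[MotifMatch]
    lipase_box: Optional[MotifMatch]
    triad: Optional[CatalyticTriad]
    order_ok: bool
    passes: bool
    classification: str
    cleavage_site: Optional[int] = None


# ---------------------------------------------------------------------------
# Filters


def is_secreted(
    protein: ProteinRecord,
    calls: Sequence[SignalPeptideCall],
    config: ScreenConfig,
) -> tuple[bool, Optional[int]]:
    """Secretion verdict for one protein from the call table.

    With no call for the protein, the toy heuristic applies when enabled
    (``sp_fallback_enabled``); otherwise the protein counts as not secreted.
    Conflicting duplicate calls are an error.
    """
    matching = [c for c in calls if c.protein_id == protein.id]
    if matching:
        first = matching[0]
        for other in matching[1:]:
            if (other.is_secreted, other.cleavage_site) != (first.is_secreted, first.cleavage_site):
                raise ScreenError(f"conflicting signal-peptide calls for {protein.id}")
        return first.is_secreted, first.cleavage_site
    if config.sp_fallback_enabled:
        return _toy_signal_peptide(protein.sequence)
    return False, None


def _toy_signal_peptide(seq: str) -> tuple[bool, Optional[int]]:
    """Minimal n/h/c-region signal-peptide heuristic (never a SignalP substitute).

    Secreted iff residue 1 is Met, a Lys/Arg occurs within residues 1-5, and
    some window of >=8 consecutive residues within residues 3-35 has mean
    Kyte-Doolittle hydropathy >= 1.5. The cleavage site is the end of the
    first such window (leftmost start, then shortest) plus 5, capped at 45.
    """
    if not seq or seq[0] != "M":
        return False, None
    if not any(c in "KR" for c in seq[:5]):
        return False, None
    lo, hi = 2, min(35, len(seq))  # residues 3..35, 0-based [lo, hi)
    for start in range(lo, hi):
        for end in range(start + 8, hi + 1):
            window = seq[start:end]
            score = sum(_KYTE_DOOLITTLE.get(c, 0.0) for c in window) / len(window)
            if score >= 1.5:
                # window end (1-based) is `end`; site = window end + 5, capped
                site = min(end + 5, 45)
                if site > len(seq):
                    return False, None
                return True, site
    return False, None


def has_abh_fold(
    protein_id: str, hits: Sequence[DomainHit], config: ScreenConfig
) -> bool:
    """True iff any domain hit marks the protein as an alpha/beta hydrolase."""
    for h in hits:
        if h.protein_id != protein_id:
            continue
        if h.signature_id in config.fold_signature_ids:
            return True
        desc = h.description.lower()
        if any(k.lower() in desc for k in config.fold_description_keywords):
            return True
    return False


# ---------------------------------------------------------------------------
# Motif stage


def _scan_all(sequence: str, patterns: Iterable[MotifPattern], offset: int) -> list[MotifMatch]:
    out: list[MotifMatch] = []
    for p in patterns:
        for m in scan(sequence, p):
            out.append(
                replace(
                    m,
                    start=m.start + offset,
                    end=m.end + offset,
                    serine_pos=(m.serine_pos + offset) if m.serine_pos else None,
                )
            )
    out.sort(key=lambda m: (m.start, m.end, m.pattern_name))
    return out


def screen_protein(
    protein: ProteinRecord,
    calls: Sequence[SignalPeptideCall],
    hits: Sequence[DomainHit],
    config: ScreenConfig,
) -> CandidateReport:
    """Run the full screen on one protein.

    Motifs are searched in the mature sequence (downstream of the cleavage
    site) when ``search_region == "mature"`` and a site is known; coordinates
    are reported on the full sequence either way. Among all (oxyanion,
    lipase-box) pairs, the first — by lipase-box start, then nearest upstream
    oxyanion — with a complete triad and correct feature order is recorded.
    """
    secreted, site = is_secreted(protein, calls, config)
    fold = has_abh_fold(protein.id, hits, config)

    offset = 0
    region = protein.sequence
    if config.search_region == "mature" and site is not None:
        offset = site - 1
        region = protein.sequence[offset:]

    oxy_matches = _scan_all(region, config.oxyanion_patterns, offset)
    box_matches = _scan_all(region, config.lipase_patterns, offset)

    chosen_oxy: Optional[MotifMatch] = None
    chosen_box: Optional[MotifMatch] = None
    chosen_triad: Optional[CatalyticTriad] = None
    order_ok = False
    for box in box_matches:
        triad = find_triads(protein.sequence, box)
        if triad is None:
            continue
        upstream = [o for o in oxy_matches if o.end < box.start]
        if not upstream:
            continue
        oxy = max(upstream, key=lambda o: o.start)  # nearest upstream
        if evaluate_order(oxy, box, triad):
            chosen_oxy, chosen_box, chosen_triad = oxy, box, triad
            order_ok = True
            break

    if not order_ok:
        # Best-effort feature report for a failing protein: leftmost box
        # (preferring one with a triad), its nearest oxyanion, if any.
        for box in box_matches:
            triad = find_triads(protein.sequence, box)
            if triad is not None:
                chosen_box, chosen_triad = box, triad
                break
        if chosen_box is None and box_matches:
            chosen_box = box_matches[0]
        if oxy_matches:
            if chosen_box is not None:
                upstream = [o for o in oxy_matches if o.end < chosen_box.start]
                chosen_oxy = max(upstream, key=lambda o: o.start) if upstream else oxy_matches[0]
            else:
                chosen_oxy = oxy_matches[0]

    passes = bool(
        secreted
        and fold
        and chosen_oxy is not None
        and chosen_box is not None
        and chosen_triad is not None
        and order_ok
    )
    report = CandidateReport(
        protein_id=protein.id,
        secreted=secreted,
        has_fold=fold,
        oxyanion=chosen_oxy,
        lipase_box=chosen_box,
        triad=chosen_triad,
        order_ok=order_ok,
        passes=passes,
        classification=CLASS_NONE,
        cleavage_site=site,
    )
    if passes:
        report = replace(report, classification=classify_lipase_box(report))
    return report


def classify_lipase_box(report: CandidateReport) -> str:
    """Classify a passing candidate by its matched lipase-box pattern."""
    if not report.passes or report.lipase_box is None:
        raise ScreenError("classify_lipase_box requires a passing report")
    name = report.lipase_box.pattern_name
    if name in _AHSXG_FAMILY:
        return CLASS_AHSXG
    if name == "GHSXH":
        return CLASS_GHSXH
    if name == "GXSXG":
        return CLASS_GXSXG
    return CLASS_OTHER


# ---------------------------------------------------------------------------
# Proteome level


def screen_proteome(
    proteins: Sequence[ProteinRecord],
    calls: Sequence[SignalPeptideCall],
    hits: Sequence[DomainHit],
    config: Optional[ScreenConfig] = None,
) -> tuple[list[CandidateReport], dict]:
    """Screen every protein; returns (reports in input order, summary counts)."""
    config = config or ScreenConfig()
    calls_by_id: dict[str, list[SignalPeptideCall]] = {}
    for c in calls:
        calls_by_id.setdefault(c.protein_id, []).append(c)
    hits_by_id: dict[str, list[DomainHit]] = {}
    for h in hits:
        hits_by_id.setdefault(h.protein_id, []).append(h)

    reports = [
        screen_protein(p, calls_by_id.get(p.id, []), hits_by_id.get(p.id, []), config)
        for p in proteins
    ]
    summary = {
        "n_proteins": len(reports),
        "n_secreted": sum(r.secreted for r in reports),
        "n_fold_positive": sum(r.has_fold for r in reports),
        "n_passing": sum(r.passes for r in reports),
    }
    return reports, summary


# ---------------------------------------------------------------------------
# Output writers

_REPORT_COLUMNS = [
    "protein_id", "secreted", "cleavage_site", "has_fold",
    "oxyanion_pattern", "oxyanion_start", "oxyanion_end", "oxyanion_text",
    "lipase_box_pattern", "lipase_box_start", "lipase_box_end", "lipase_box_text",
    "ser_pos", "asp_pos", "his_pos", "n_alternative_pairs",
    "order_ok", "passes", "classification",
]


def report_rows(reports: Sequence[CandidateReport]) -> list[dict]:
    rows = []
    for r in reports:
        rows.append(
            {
                "protein_id": r.protein_id,
                "secreted": int(r.secreted),
                "cleavage_site": r.cleavage_site if r.cleavage_site is not None else "",
                "has_fold": int(r.has_fold),
                "oxyanion_pattern": r.oxyanion.pattern_name if r.oxyanion else "",
                "oxyanion_start": r.oxyanion.start if r.oxyanion else "",
                "oxyanion_end": r.oxyanion.end if r.oxyanion else "",
                "oxyanion_text": r.oxyanion.matched_text if r.oxyanion else "",
                "lipase_box_pattern": r.lipase_box.pattern_name if r.lipase_box else "",
                "lipase_box_start": r.lipase_box.start if r.lipase_box else "",
                "lipase_box_end": r.lipase_box.end if r.lipase_box else "",
                "lipase_box_text": r.lipase_box.matched_text if r.lipase_box else "",
                "ser_pos": r.triad.ser_pos if r.triad else "",
                "asp_pos": r.triad.asp_pos if r.triad else "",
                "his_pos": r.triad.his_pos if r.triad else "",
                "n_alternative_pairs": r.triad.n_alternative_pairs if r.triad else "",
                "order_ok": int(r.order_ok),
                "passes": int(r.passes),
                "classification": r.classification,
            }
        )
    return rows


def write_reports(reports: Sequence[CandidateReport], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_REPORT_COLUMNS) + "\n")
        for row in report_rows(reports):
            fh.write("\t".join(str(row[c]) for c in _REPORT_COLUMNS) + "\n")


def write_summary(summary: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
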