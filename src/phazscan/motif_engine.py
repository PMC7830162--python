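"""Degenerate amino-acid motif patterns and catalytic-triad location.

Serine hydrolases of the alpha/beta-hydrolase superfamily — PHA depolymerases,
lipases, esterases — carry three conserved sequence features: an oxyanion
pocket (e.g. PXXXXHG), a pentapeptide "lipase box" containing the catalytic
serine (canonically GXSXG), and the remaining catalytic-triad residues,
aspartate then histidine, downstream of the box. This module compiles the
degenerate patterns, scans sequences for all (possibly overlapping)
occurrences, and locates triads.

Pattern grammar: uppercase amino-acid letters are literal, ``X`` is a
wildcard, ``[...]`` is an alternation group (commas inside are decorative:
``[I,T]`` is the same as ``[IT]``). An ``X`` *residue* in a sequence matches
only wildcard positions, never a literal or group position.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

from .io_formats import AMINO_ACIDS

_AA_SET = frozenset(AMINO_ACIDS)
_WILDCARD = _AA_SET  # a wildcard position accepts every residue, incl. 'X'

ROLE_OXYANION = "oxyanion"
ROLE_LIPASE_BOX = "lipase_box"
_ROLES = (ROLE_OXYANION, ROLE_LIPASE_BOX)


class PatternError(ValueError):
    """Raised for an ill-formed pattern specification."""


@dataclass(frozen=True)
class MotifPattern:
    name: str
    role: str
    spec: str
    positions: tuple[frozenset, ...]
    serine_anchor: Optional[int] = None  # 1-based offset, lipase_box only
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class MotifMatch:
    pattern_name: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    matched_text: str
    serine_pos: Optional[int] = None  # absolute 1-based, lipase_box only


@dataclass(frozen=True)
class CatalyticTriad:
    ser_pos: int
    asp_pos: int
    his_pos: int
    n_alternative_pairs: int = 1

    def __post_init__(self) -> None:
        if not (self.ser_pos < self.asp_pos < self.his_pos):
            raise ValueError(
                f"triad positions must be ordered Ser<Asp<His, got "
                f"{self.ser_pos}, {self.asp_pos}, {self.his_pos}"
            )


def compile_pattern(spec: str, name: str, role: str, provenance: str = "") -> MotifPattern:
    """Compile a degenerate pattern string into a :class:`MotifPattern`.

    For a lipase box, exactly one position must be the literal serine ``{S}``;
    that position becomes the serine anchor.
    """
    if role not in _ROLES:
        raise PatternError(f"pattern {name}: unknown role {role!r}")
    positions: list[frozenset] = []
    i = 0
    while i < len(spec):
        c = spec[i]
        if c == "X":
            positions.append(_WILDCARD)
            i += 1
        elif c == "[":
            j = spec.find("]", i)
            if j < 0:
                raise PatternError(f"pattern {name}: unclosed '[' at offset {i + 1}")
            letters = [ch for ch in spec[i + 1 : j] if ch != ","]
            if not letters:
                raise PatternError(f"pattern {name}: empty bracket group at offset {i + 1}")
            bad = [ch for ch in letters if ch not in _AA_SET]
            if bad:
                raise PatternError(f"pattern {name}: illegal character {bad[0]!r} in group")
            positions.append(frozenset(letters))
            i = j + 1
        elif c in _AA_SET:
            positions.append(frozenset(c))
            i += 1
        else:
            raise PatternError(f"pattern {name}: illegal character {c!r} at offset {i + 1}")
    if len(positions) < 3:
        raise PatternError(f"pattern {name}: must have >=3 positions, got {len(positions)}")
    anchor = None
    if role == ROLE_LIPASE_BOX:
        s_only = [k + 1 for k, p in enumerate(positions) if p == frozenset("S")]
        if len(s_only) != 1:
            raise PatternError(
                f"pattern {name}: lipase box needs exactly one S-only position, "
                f"found {len(s_only)}"
            )
        anchor = s_only[0]
    return MotifPattern(
        name=name,
        role=role,
        spec=spec,
        positions=tuple(positions),
        serine_anchor=anchor,
        provenance=provenance,
    )


def scan(sequence: str, pattern: MotifPattern) -> list[MotifMatch]:
    """Find all (possibly overlapping) occurrences of ``pattern``, by start.

    An ``X`` in the sequence matches only wildcard positions: an unknown
    residue is never allowed to satisfy a literal constraint.
    """
    n, m = len(sequence), len(pattern)
    matches: list[MotifMatch] = []
    for start in range(n - m + 1):
        ok = True
        for k, allowed in enumerate(pattern.positions):
            c = sequence[start + k]
            if c == "X":
                if allowed != _WILDCARD:
                    ok = False
                    break
            elif c not in allowed:
                ok = False
                break
        if ok:
            ser = start + pattern.serine_anchor if pattern.serine_anchor else None
            matches.append(
                MotifMatch(
                    pattern_name=pattern.name,
                    start=start + 1,
                    end=start + m,
                    matched_text=sequence[start : start + m],
                    serine_pos=ser,
                )
            )
    return matches


def find_triads(sequence: str, lipase_match: MotifMatch) -> Optional[CatalyticTriad]:
    """Locate the catalytic triad completing a lipase-box match.

    Considers every Asp strictly downstream of the box and every His
    downstream of that Asp. Returns the triad with the smallest Asp position,
    then the smallest His position; ``n_alternative_pairs`` counts all valid
    (Asp, His) pairs. Structure-free tie-breaking: the true residues can only
    be pinned down by alignment to solved structures, so the leftmost pair is
    reported and the ambiguity quantified.
    """
    if lipase_match.serine_pos is None:
        raise ValueError("find_triads requires a lipase-box match with a serine position")
    d_positions = [i + 1 for i in range(lipase_match.end, len(sequence)) if sequence[i] == "D"]
    h_positions = [i + 1 for i in range(lipase_match.end, len(sequence)) if sequence[i] == "H"]
    if not d_positions or not h_positions:
        return None
    n_pairs = 0
    best: Optional[tuple[int, int]] = None
    for d in d_positions:
        hs = [h for h in h_positions if h > d]
        n_pairs += len(hs)
        if hs and best is None:
            best = (d, hs[0])
    if best is None:
        return None
    return CatalyticTriad(
        ser_pos=lipase_match.serine_pos,
        asp_pos=best[0],
        his_pos=best[1],
        n_alternative_pairs=n_pairs,
    )


def evaluate_order(
    oxyanion: MotifMatch, lipase: MotifMatch, triad: CatalyticTriad
) -> bool:
    """True iff the features appear in the canonical depolymerase order.

    The oxyanion pocket must lie strictly upstream of (and not overlap) the
    lipase box, and the triad must run Ser < Asp < His.
    """
    return (
        oxyanion.end < lipase.start
        and triad.ser_pos < triad.asp_pos < triad.his_pos
    )


# ---------------------------------------------------------------------------
# Default pattern library

_DATA = resources.files("phazscan") / "data"


def load_pattern_library(path: str | Path | None = None) -> list[MotifPattern]:
    """Load a pattern library from YAML (default: the packaged library)."""
    if path is None:
        text = (_DATA / "patterns.yaml").read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    entries = yaml.safe_load(text)
    patterns = [
        compile_pattern(
            e["spec"], name=e["name"], role=e["role"], provenance=e.get("provenance", "")
        )
        for e in entries
    ]
    names = [p.name for p in patterns]
    if len(set(names)) != len(names):
        raise PatternError("duplicate pattern names in library")
    return patterns


def default_patterns() -> list[MotifPattern]:
    return load_pattern_library(None)
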