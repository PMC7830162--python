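"""PHA-cycle metabolic-potential profiling of annotated genomes.

The PHA cycle couples biosynthesis (acyl-CoA -> oxoacyl-CoA -> hydroxyacyl-CoA
-> PHA, via PhaA/BktB, then FabG/FadB/Hbd/PhaB, then the synthase PhaC) to
degradation (PHA -> monomer by PhaZ/PhaY, monomer -> oxo acid by Bdh or Hpd,
oxo acid -> acyl-CoA by AacS or ScoA/ScoB). This module encodes the cycle as
a gene-function catalog with EC-number and keyword matchers, turns per-genome
annotation tables into presence/absence profiles, and derives pathway
completeness calls from the profiles.

Extracellular vs intracellular depolymerases (phaZ_e vs phaZ_i) are
distinguished by the signal-peptide status of the annotated protein: a PhaZ
without a predicted signal peptide is counted as intracellular.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .io_formats import AnnotationFeature, SignalPeptideCall

#: The 12 core gene functions of the reference presence/absence table, in
#: display order, followed by the 4 alternate-route functions.
CORE_KEYS = (
    "phaA_bktB", "fabG", "fadB", "hbd", "phaB", "phaC",
    "phaY_e", "phaZ_e", "phaZ_i", "bdh", "aacS", "scoAB",
)
ALTERNATE_KEYS = ("phaJ", "phaG", "hpd", "hibdh")
ALL_KEYS = CORE_KEYS + ALTERNATE_KEYS


class ProfileError(ValueError):
    pass


@dataclass(frozen=True)
class GeneFunction:
    key: str
    ec_numbers: tuple[str, ...] = ()
    name_keywords: tuple[str, ...] = ()
    localization: str = "any"  # extracellular | intracellular | any
    #: EC prefix gate for functions whose catalog EC is too coarse on its own
    #: (e.g. the synthase's "2.3.1.-" would also match the ketothiolase).
    ec_prefix_gate: Optional[str] = None
    #: For multi-subunit functions: every keyword set must be matched by some
    #: feature for the function to count as present.
    requires_all_of: tuple[tuple[str, ...], ...] = ()


@dataclass(frozen=True)
class PathwayCall:
    """Completeness flags for one genome, derived from gene presence."""

    genome_id: str
    monomer_supply: bool
    biosynthesis_complete: bool
    depoly_extracellular: bool
    monomer_oxidation: str  # yes | no | partial_3C
    coa_activation: bool
    intracellular_utilization: bool
    full_intracellular_cycle: bool


@dataclass(frozen=True)
class PresenceAbsenceMatrix:
    genome_ids: tuple[str, ...]
    function_keys: tuple[str, ...]
    values: tuple[tuple[bool, ...], ...]  # rows = genomes

    def __post_init__(self) -> None:
        if len(self.values) != len(self.genome_ids) or any(
            len(row) != len(self.function_keys) for row in self.values
        ):
            raise ProfileError("matrix dimensions do not match the id lists")

    def row(self, genome_id: str) -> dict[str, bool]:
        i = self.genome_ids.index(genome_id)
        return dict(zip(self.function_keys, self.values[i]))


def build_function_catalog(
    overrides: Optional[Iterable[GeneFunction]] = None,
) -> list[GeneFunction]:
    """The default 16-function catalog (12 core + 4 alternate-route).

    The synthase (phaC) and the hydroxyacyl-CoA-ACP transferase (phaG) carry
    incomplete EC numbers in annotation practice, so they are keyword-gated:
    a name keyword is required and any EC present must agree with the gated
    EC-class prefix.
    """
    catalog = [
        GeneFunction("phaA_bktB", ("2.3.1.9", "2.3.1.16"),
                     ("acetyl-coa acetyltransferase", "ketothiolase")),
        GeneFunction("fabG", ("1.1.1.100",),
                     ("3-oxoacyl-[acyl-carrier-protein] reductase", "3-oxoacyl-acp reductase")),
        GeneFunction("fadB", ("4.2.1.17", "1.1.1.35"),
                     ("multifunctional enoyl-coa hydratase", "3-hydroxyacyl-coa dehydrogenase")),
        GeneFunction("hbd", ("1.1.1.157",), ("3-hydroxybutyryl-coa dehydrogenase",)),
        GeneFunction("phaB", ("1.1.1.36",), ("acetoacetyl-coa reductase",)),
        GeneFunction("phaC", (),
                     ("pha synthase", "polyhydroxyalkano", "poly(3-hydroxy", "pha polymerase"),
                     ec_prefix_gate="2.3.1"),
        GeneFunction("phaY_e", ("3.1.1.22",),
                     ("pha oligomer hydrolase", "hydroxybutyrate oligomer hydrolase"),
                     localization="extracellular"),
        GeneFunction("phaZ_e", ("3.1.1.75", "3.1.1.76"),
                     ("pha depolymerase", "polyhydroxyalkanoate depolymerase",
                      "polyhydroxybutyrate depolymerase"),
                     localization="extracellular"),
        GeneFunction("phaZ_i", ("3.1.1.75", "3.1.1.76"),
                     ("pha depolymerase", "polyhydroxyalkanoate depolymerase",
                      "polyhydroxybutyrate depolymerase"),
                     localization="intracellular"),
        GeneFunction("bdh", ("1.1.1.30",), ("3-hydroxybutyrate dehydrogenase",)),
        GeneFunction("aacS", ("6.2.1.16",), ("acetoacetyl-coa synthetase",)),
        GeneFunction("scoAB", ("2.8.3.5",), ("3-oxoacid coa-transferase",),
                     requires_all_of=(("subunit a",), ("subunit b",))),
        GeneFunction("phaJ", ("4.2.1.119",), ("(r)-specific enoyl-coa hydratase",)),
        GeneFunction("phaG", (),
                     ("hydroxyacyl-coa-acyl carrier protein transferase",
                      "hydroxyacyl-coa-[acyl-carrier-protein] transferase"),
                     ec_prefix_gate="2.4.1"),
        GeneFunction("hpd", ("1.1.1.59",), ("3-hydroxypropionate dehydrogenase",)),
        GeneFunction("hibdh", ("1.1.1.31",), ("3-hydroxyisobutyrate dehydrogenase",)),
    ]
    if overrides is not None:
        catalog = list(overrides)
    keys = [f.key for f in catalog]
    if len(set(keys)) != len(keys):
        raise ProfileError("duplicate keys in function catalog")
    return catalog


def _ec_matches(catalog_ec: str, feature_ec: str) -> bool:
    """Exact EC match; '-' in the catalog EC is a one-field wildcard."""
    ca, fa = catalog_ec.split("."), feature_ec.split(".")
    if len(ca) != 4 or len(fa) != 4:
        return False
    return all(c == "-" or c == f for c, f in zip(ca, fa))


def _feature_matches(func: GeneFunction, feat: AnnotationFeature) -> bool:
    text = feat.function_text.lower()
    if func.ec_prefix_gate is not None:
        if not any(k in text for k in func.name_keywords):
            return False
        if feat.ec_numbers and not any(
            ec.startswith(func.ec_prefix_gate + ".") for ec in feat.ec_numbers
        ):
            return False
        return True
    if any(_ec_matches(cec, fec) for cec in func.ec_numbers for fec in feat.ec_numbers):
        return True
    return any(k in text for k in func.name_keywords)


def detect_functions(
    features: Sequence[AnnotationFeature],
    catalog: Optional[Sequence[GeneFunction]] = None,
    sp_calls: Optional[Sequence[SignalPeptideCall]] = None,
) -> dict[str, bool]:
    """Presence/absence of every catalog function in one genome's features.

    Localized functions (phaZ_e/phaZ_i, phaY_e) are resolved through the
    signal-peptide calls of the linked proteins: a depolymerase whose protein
    has no secreted call counts as intracellular, mirroring how annotation
    without a signal peptide is interpreted.
    """
    catalog = catalog if catalog is not None else build_function_catalog()
    secreted_ids = {
        c.protein_id for c in (sp_calls or []) if c.is_secreted
    }
    presence: dict[str, bool] = {}
    for func in catalog:
        hits = [f for f in features if _feature_matches(func, f)]
        if func.requires_all_of:
            present = all(
                any(
                    all(k in f.function_text.lower() for k in kw_set)
                    for f in hits
                )
                for kw_set in func.requires_all_of
            ) and bool(hits)
        elif func.localization == "extracellular":
            present = any(f.protein_id in secreted_ids for f in hits)
        elif func.localization == "intracellular":
            present = any(f.protein_id not in secreted_ids for f in hits)
        else:
            present = bool(hits)
        presence[func.key] = present
    return presence


def call_pathways(
    presence: Mapping[str, bool],
    catalog: Optional[Sequence[GeneFunction]] = None,
    genome_id: str = "",
) -> PathwayCall:
    """Derive PHA-cycle completeness flags from a gene-presence map.

    The 3-hydroxyisobutyrate dehydrogenase (hibdh) route only yields a
    ``partial_3C`` oxidation verdict — it acts on 3-carbon monomers with a
    much higher K_M and does not substitute for bdh/hpd — so it never grants
    full intracellular utilization.
    """
    catalog = catalog if catalog is not None else build_function_catalog()
    valid = {f.key for f in catalog}
    unknown = set(presence) - valid
    if unknown:
        raise ProfileError(f"unknown function keys in presence map: {sorted(unknown)}")
    get = lambda k: bool(presence.get(k, False))

    monomer_supply = (
        get("phaA_bktB") and (get("fabG") or get("fadB") or get("hbd") or get("phaB"))
    ) or get("phaJ") or get("phaG")
    biosynthesis_complete = monomer_supply and get("phaC")
    depoly_extracellular = get("phaZ_e") or get("phaY_e")
    if get("bdh") or get("hpd"):
        monomer_oxidation = "yes"
    elif get("hibdh"):
        monomer_oxidation = "partial_3C"
    else:
        monomer_oxidation = "no"
    coa_activation = get("aacS") or get("scoAB")
    intracellular_utilization = monomer_oxidation == "yes" and coa_activation
    full_intracellular_cycle = (
        biosynthesis_complete and get("phaZ_i") and intracellular_utilization
    )
    return PathwayCall(
        genome_id=genome_id,
        monomer_supply=monomer_supply,
        biosynthesis_complete=biosynthesis_complete,
        depoly_extracellular=depoly_extracellular,
        monomer_oxidation=monomer_oxidation,
        coa_activation=coa_activation,
        intracellular_utilization=intracellular_utilization,
        full_intracellular_cycle=full_intracellular_cycle,
    )


def profile_genomes(
    tables: Mapping[str, Sequence[AnnotationFeature]],
    catalog: Optional[Sequence[GeneFunction]] = None,
    sp_calls: Optional[Sequence[SignalPeptideCall]] = None,
) -> tuple[PresenceAbsenceMatrix, list[PathwayCall]]:
    """Profile several genomes: presence matrix plus pathway calls.

    The matrix covers the 12 core functions plus any alternate-route function
    detected in at least one genome; row order follows the input mapping.
    """
    catalog = catalog if catalog is not None else build_function_catalog()
    genome_ids = tuple(tables.keys())
    maps = {g: detect_functions(tables[g], catalog, sp_calls) for g in genome_ids}
    extra = tuple(
        k for k in ALTERNATE_KEYS if any(maps[g].get(k, False) for g in genome_ids)
    )
    keys = tuple(CORE_KEYS) + extra
    matrix = PresenceAbsenceMatrix(
        genome_ids=genome_ids,
        function_keys=keys,
        values=tuple(tuple(maps[g].get(k, False) for k in keys) for g in genome_ids),
    )
    calls = [call_pathways(maps[g], catalog, genome_id=g) for g in genome_ids]
    return matrix, calls


# ---------------------------------------------------------------------------
# Packaged reference matrix (transcribed published gene-content table)

_FIXTURE = resources.files("phazscan") / "data" / "table4_gene_matrix.tsv"

#: Footnote tag meaning: deposited as an extracellular depolymerase but the
#: protein carries no predicted signal peptide; the printed tick is kept in
#: the matrix, but pathway calling does not count it as extracellular.
NO_SP_FOOTNOTE = "no_signal_peptide"


@dataclass(frozen=True)
class ReferenceMatrix:
    matrix: PresenceAbsenceMatrix
    members: tuple[str, ...]  # consortium-member genome ids
    footnotes: dict = field(default_factory=dict)  # genome_id -> {key: tag}


def load_reference_matrix(path: str | Path | None = None) -> ReferenceMatrix:
    """Load the packaged 33-genome presence/absence matrix (or a compatible TSV)."""
    text = (
        (_FIXTURE).read_text(encoding="utf-8")
        if path is None
        else Path(path).read_text(encoding="utf-8")
    )
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    keys = tuple(header[2:-1])
    genome_ids: list[str] = []
    rows: list[tuple[bool, ...]] = []
    members: list[str] = []
    footnotes: dict[str, dict[str, str]] = {}
    for ln in lines[1:]:
        cols = ln.split("\t")
        cols += [""] * (len(header) - len(cols))
        gid = cols[0]
        genome_ids.append(gid)
        if cols[1] == "1":
            members.append(gid)
        row = []
        for cell in cols[2 : 2 + len(keys)]:
            if cell == "✓":
                row.append(True)
            elif cell == "-":
                row.append(False)
            else:
                raise ProfileError(f"bad matrix cell {cell!r} for {gid}")
        rows.append(tuple(row))
        note = cols[2 + len(keys)].strip()
        if note:
            fk, tag = note.split(":", 1)
            footnotes[gid] = {fk: tag}
    matrix = PresenceAbsenceMatrix(
        genome_ids=tuple(genome_ids), function_keys=keys, values=tuple(rows)
    )
    return ReferenceMatrix(matrix=matrix, members=tuple(members), footnotes=footnotes)


def call_pathways_for_matrix(
    ref: ReferenceMatrix, catalog: Optional[Sequence[GeneFunction]] = None
) -> list[PathwayCall]:
    """Pathway calls for every genome of a presence/absence matrix.

    Footnoted entries tagged :data:`NO_SP_FOOTNOTE` are treated as not
    extracellular for pathway purposes while staying ticked in the matrix.
    """
    calls = []
    for gid in ref.matrix.genome_ids:
        presence = ref.matrix.row(gid)
        for fk, tag in ref.footnotes.get(gid, {}).items():
            if tag == NO_SP_FOOTNOTE:
                presence[fk] = False
        calls.append(call_pathways(presence, catalog, genome_id=gid))
    return calls


# ---------------------------------------------------------------------------
# Writers

def write_matrix(matrix: PresenceAbsenceMatrix, path: str | Path, style: str = "check") -> None:
    """Write a matrix TSV; ``style`` is 'check' (✓/-) or 'binary' (1/0)."""
    t, f = ("✓", "-") if style == "check" else ("1", "0")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("genome_id\t" + "\t".join(matrix.function_keys) + "\n")
        for gid, row in zip(matrix.genome_ids, matrix.values):
            fh.write(gid + "\t" + "\t".join(t if v else f for v in row) + "\n")


_PATHWAY_COLUMNS = [
    "genome_id", "monomer_supply", "biosynthesis_complete", "depoly_extracellular",
    "monomer_oxidation", "coa_activation", "intracellular_utilization",
    "full_intracellular_cycle",
]


def write_pathway_calls(calls: Sequence[PathwayCall], path: str | Path) -> None:
    def cell(v):
        return str(int(v)) if isinstance(v, bool) else str(v)

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_PATHWAY_COLUMNS) + "\n")
        for c in calls:
            fh.write("\t".join(cell(getattr(c, col)) for col in _PATHWAY_COLUMNS) + "\n")
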