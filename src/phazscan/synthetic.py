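"""Seeded generator of benchmark proteomes with planted screen features.

Each generated protein is either a *candidate* — a signal peptide, an
alpha/beta-hydrolase fold annotation, and the conserved features planted in
valid order (oxyanion pocket, lipase box, catalytic Asp, catalytic His) — or
a decoy that violates exactly one of the screen's criteria and satisfies all
the others. After assembly every protein is re-screened and resampled if a
chance arrangement of background residues produced an unintended outcome, so
the emitted ground truth is exact by construction.

The generator also emits annotation feature tables realizing arbitrary
gene-content profiles, for round-tripping the PHA-cycle profiler.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .io_formats import (
    AMINO_ACIDS,
    AnnotationFeature,
    DomainHit,
    ProteinRecord,
    SignalPeptideCall,
    write_fasta,
    write_interproscan,
    write_signalp_generic,
)
from .motif_engine import ROLE_LIPASE_BOX, ROLE_OXYANION
from .profiler import GeneFunction, build_function_catalog
from .screen import ScreenConfig, screen_protein

LABEL_CANDIDATE = "candidate"
DECOY_LABELS = (
    "no_sp",
    "no_fold",
    "missing_oxyanion",
    "missing_lipase_box",
    "missing_asp",
    "missing_his",
    "wrong_order",
)
ALL_LABELS = (LABEL_CANDIDATE,) + DECOY_LABELS


class GeneratorError(RuntimeError):
    pass


@dataclass(frozen=True)
class SyntheticTruth:
    protein_id: str
    label: str
    #: feature_role -> (1-based start, planted text)
    planted: dict = field(default_factory=dict)


def _default_background() -> np.ndarray:
    # Uniform over the 20 amino acids, with the motif-seeding residues
    # P, H, G, S, D down-weighted by 20% to reduce accidental motifs.
    w = np.ones(len(AMINO_ACIDS))
    for aa in "PHGSD":
        w[AMINO_ACIDS.index(aa)] *= 0.8
    return w / w.sum()


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 42
    n_per_class: Mapping[str, int] = field(
        default_factory=lambda: {label: 20 for label in ALL_LABELS}
    )
    length_range: tuple[int, int] = (250, 450)  # mature-region residues
    background: np.ndarray = field(default_factory=_default_background)
    #: (number of charged n-region residues, h-region length, cleavage motif)
    sp_template: tuple[int, int, str] = (2, 12, "AQA")
    flank_min: int = 10

    def __post_init__(self) -> None:
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (len(AMINO_ACIDS),) or (bg < 0).any() or abs(bg.sum() - 1) > 1e-9:
            raise GeneratorError("background must be 20 non-negative frequencies summing to 1")
        object.__setattr__(self, "background", bg)
        for label in self.n_per_class:
            if label not in ALL_LABELS:
                raise GeneratorError(f"unknown label {label!r}")


_AA = np.array(list(AMINO_ACIDS))


def _sample_bg(rng: np.random.Generator, n: int, cfg: GeneratorConfig,
               exclude: str = "") -> str:
    if n <= 0:
        return ""
    if exclude:
        keep = np.array([aa not in exclude for aa in AMINO_ACIDS])
        w = cfg.background * keep
        w = w / w.sum()
    else:
        w = cfg.background
    return "".join(rng.choice(_AA, size=n, p=w))


def _signal_peptide(rng: np.random.Generator, cfg: GeneratorConfig) -> str:
    n_charged, h_len, cleave = cfg.sp_template
    n_region = "".join(rng.choice(np.array(list("KR")), size=n_charged))
    h_region = "".join(rng.choice(np.array(list("LIVFA")), size=h_len))
    return "M" + n_region + h_region + cleave


def _instantiate(rng: np.random.Generator, spec_positions, cfg: GeneratorConfig,
                 exclude: str = "") -> str:
    """Concretize a motif pattern: wildcards from background, groups uniformly."""
    out = []
    for pos in spec_positions:
        if len(pos) == len(AMINO_ACIDS):  # wildcard
            out.append(_sample_bg(rng, 1, cfg, exclude=exclude))
        else:
            choices = sorted(pos)
            out.append(choices[rng.integers(len(choices))])
    return "".join(out)


# Which criteria each decoy class is meant to break (all others must hold).
# Expected report flag signature per label:
#   (secreted, has_fold, oxyanion?, lipase_box?, triad?, order_ok, passes)
_EXPECTED = {
    LABEL_CANDIDATE: (True, True, True, True, True, True, True),
    "no_sp": (False, True, True, True, True, True, False),
    "no_fold": (True, False, True, True, True, True, False),
    "missing_oxyanion": (True, True, False, True, True, False, False),
    "missing_lipase_box": (True, True, True, False, False, False, False),
    "missing_asp": (True, True, True, True, False, False, False),
    "missing_his": (True, True, True, True, False, False, False),
    "wrong_order": (True, True, True, True, True, False, False),
}


def _report_signature(report) -> tuple:
    return (
        report.secreted,
        report.has_fold,
        report.oxyanion is not None,
        report.lipase_box is not None,
        report.triad is not None,
        report.order_ok,
        report.passes,
    )


def generate_protein(
    label: str,
    config: GeneratorConfig,
    rng: np.random.Generator,
    protein_id: str = "syn1",
    screen_config: Optional[ScreenConfig] = None,
) -> tuple[ProteinRecord, SignalPeptideCall, list[DomainHit], SyntheticTruth]:
    """Generate one protein of the requested truth class.

    The sequence is assembled from a signal peptide (omitted for ``no_sp``),
    background residues and the planted features, then re-screened; if chance
    background created an unintended feature chain (or destroyed the intended
    one) the protein is resampled, up to 100 times.
    """
    if label not in ALL_LABELS:
        raise GeneratorError(f"unknown label {label!r}")
    screen_config = screen_config or ScreenConfig()
    lipase_patterns = [p for p in screen_config.pattern_library if p.role == ROLE_LIPASE_BOX]
    oxy_pattern = next(
        p for p in screen_config.pattern_library
        if p.role == ROLE_OXYANION and p.name == "PXXXXHG"
    )

    for _attempt in range(100):
        secreted = label != "no_sp"
        sp = _signal_peptide(rng, config) if secreted else ""
        cleavage_site = len(sp) + 1 if secreted else None

        box_pattern = lipase_patterns[rng.integers(len(lipase_patterns))]
        # Oxyanion instance: wildcards avoid D/H so the pocket itself cannot
        # seed a triad, and S so it cannot seed a lipase box.
        oxy_text = _instantiate(rng, oxy_pattern.positions, config, exclude="DHS")
        box_text = _instantiate(rng, box_pattern.positions, config, exclude="DH")

        parts: list[tuple[str, str]] = []  # (role, text)
        if label == "wrong_order":
            parts = [("lipase_box", box_text), ("oxyanion", oxy_text), ("asp", "D"), ("his", "H")]
        else:
            parts = [("oxyanion", oxy_text), ("lipase_box", box_text), ("asp", "D"), ("his", "H")]
            if label == "missing_oxyanion":
                parts = [p for p in parts if p[0] != "oxyanion"]
            elif label == "missing_lipase_box":
                parts = [p for p in parts if p[0] != "lipase_box"]
            elif label == "missing_asp":
                parts = [p for p in parts if p[0] != "asp"]
            elif label == "missing_his":
                parts = [p for p in parts if p[0] != "his"]

        mature_len = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        feat_len = sum(len(t) for _, t in parts)
        k = len(parts)
        min_needed = feat_len + config.flank_min * (k + 1)
        if mature_len < min_needed:
            mature_len = min_needed
        slack = mature_len - min_needed
        # k+1 gaps, each at least flank_min, slack spread at random
        extra = rng.multinomial(slack, np.ones(k + 1) / (k + 1))
        gaps = [config.flank_min + int(e) for e in extra]

        # Downstream of the lipase box the background contains no Asp/His:
        # the planted triad residues are then the only ones the screen can
        # find, so planted coordinates are recovered exactly and the
        # missing_asp/missing_his classes stay missing.
        exclude_after_box = "DH"

        mature_parts: list[str] = []
        pos = len(sp)  # 0-based position within full sequence
        planted: dict[str, tuple[int, str]] = {}
        box_seen = False
        for gap, (role, text) in zip(gaps, parts):
            excl = exclude_after_box if box_seen else ""
            mature_parts.append(_sample_bg(rng, gap, config, exclude=excl))
            pos += gap
            planted[role] = (pos + 1, text)
            mature_parts.append(text)
            pos += len(text)
            if role == "lipase_box":
                box_seen = True
        mature_parts.append(
            _sample_bg(rng, gaps[-1], config, exclude=exclude_after_box if box_seen else "")
        )
        sequence = sp + "".join(mature_parts)

        protein = ProteinRecord(id=protein_id, sequence=sequence, description=f"{protein_id} {label}")
        call = SignalPeptideCall(
            protein_id=protein_id,
            is_secreted=secreted,
            cleavage_site=cleavage_site,
            score=0.9 if secreted else 0.1,
        )
        hits: list[DomainHit] = []
        if label != "no_fold":
            span = [s for s, _ in planted.values()] or [1]
            ends = [s + len(t) - 1 for s, t in planted.values()] or [len(sequence)]
            hits.append(
                DomainHit(
                    protein_id=protein_id,
                    analysis="SUPERFAMILY",
                    signature_id="SSF53474",
                    description="alpha/beta-Hydrolases",
                    start=min(span),
                    end=max(ends),
                    evalue=1e-40,
                    interpro_id="IPR029058",
                )
            )

        report = screen_protein(protein, [call], hits, screen_config)
        if _report_signature(report) != _EXPECTED[label]:
            continue
        if label == LABEL_CANDIDATE:
            # the screen must recover exactly the planted chain
            if (
                report.lipase_box.start != planted["lipase_box"][0]
                or report.oxyanion.start != planted["oxyanion"][0]
                or report.triad.asp_pos != planted["asp"][0]
                or report.triad.his_pos != planted["his"][0]
            ):
                continue
        truth = SyntheticTruth(protein_id=protein_id, label=label, planted=planted)
        return protein, call, hits, truth

    raise GeneratorError(f"resampling failed 100 times for label {label!r} (seed {config.seed})")


@dataclass(frozen=True)
class SyntheticProteome:
    proteins: list
    sp_calls: list
    domain_hits: list
    truths: list


def generate_proteome(
    config: Optional[GeneratorConfig] = None,
    out_dir: str | Path | None = None,
    screen_config: Optional[ScreenConfig] = None,
) -> SyntheticProteome:
    """Generate a full labelled proteome; optionally write the file set.

    Files written under ``out_dir``: ``proteome.faa``, ``signalp.tsv``
    (generic dialect), ``domains.tsv`` (InterProScan dialect) and
    ``truth.tsv``. All outputs are pure functions of the config.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    proteins, calls, hits, truths = [], [], [], []
    for label in ALL_LABELS:
        for i in range(1, int(config.n_per_class.get(label, 0)) + 1):
            pid = f"syn{label}{i}"
            p, c, h, t = generate_protein(label, config, rng, protein_id=pid,
                                          screen_config=screen_config)
            proteins.append(p)
            calls.append(c)
            hits.extend(h)
            truths.append(t)
    result = SyntheticProteome(proteins, calls, hits, truths)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(proteins, out / "proteome.faa")
        write_signalp_generic(calls, out / "signalp.tsv")
        write_interproscan(hits, out / "domains.tsv")
        write_truth(truths, out / "truth.tsv")
    return result


def write_truth(truths: Sequence[SyntheticTruth], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_id\tlabel\tplanted\n")
        for t in truths:
            planted = ";".join(
                f"{role}:{start}:{text}" for role, (start, text) in sorted(t.planted.items())
            )
            fh.write(f"{t.protein_id}\t{t.label}\t{planted}\n")


def read_truth(path: str | Path) -> list[SyntheticTruth]:
    truths = []
    with open(path, encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            planted = {}
            if len(cols) > 2 and cols[2]:
                for item in cols[2].split(";"):
                    role, start, text = item.split(":")
                    planted[role] = (int(start), text)
            truths.append(SyntheticTruth(protein_id=cols[0], label=cols[1], planted=planted))
    return truths


# ---------------------------------------------------------------------------
# Annotation-table generation for the PHA-cycle profiler

#: Feature templates: function text and EC emitted to trigger exactly one
#: catalog function. phaC/phaG go through their keyword gates.
_FEATURE_TEMPLATES: dict[str, tuple[str, str]] = {
    "phaA_bktB": ("Acetyl-CoA acetyltransferase (PhaA)", "2.3.1.9"),
    "fabG": ("3-oxoacyl-[acyl-carrier-protein] reductase", "1.1.1.100"),
    "fadB": ("Multifunctional enoyl-CoA hydratase (FadB)", "4.2.1.17"),
    "hbd": ("3-hydroxybutyryl-CoA dehydrogenase", "1.1.1.157"),
    "phaB": ("Acetoacetyl-CoA reductase", "1.1.1.36"),
    "phaC": ("Polyhydroxyalkanoate synthase PhaC", "2.3.1.-"),
    "phaY_e": ("PHA oligomer hydrolase", "3.1.1.22"),
    "phaZ_e": ("Polyhydroxyalkanoate depolymerase", "3.1.1.75"),
    "phaZ_i": ("Polyhydroxyalkanoate depolymerase", "3.1.1.75"),
    "bdh": ("3-hydroxybutyrate dehydrogenase", "1.1.1.30"),
    "aacS": ("Acetoacetyl-CoA synthetase", "6.2.1.16"),
    "phaJ": ("(R)-specific enoyl-CoA hydratase PhaJ", "4.2.1.119"),
    "phaG": ("Hydroxyacyl-CoA-acyl carrier protein transferase PhaG", "2.4.1.-"),
    "hpd": ("3-hydroxypropionate dehydrogenase", "1.1.1.59"),
    "hibdh": ("3-hydroxyisobutyrate dehydrogenase", "1.1.1.31"),
}


def generate_annotation_set(
    profile: Mapping[str, Mapping[str, bool]],
    config: Optional[GeneratorConfig] = None,
    catalog: Optional[Sequence[GeneFunction]] = None,
) -> tuple[dict[str, list[AnnotationFeature]], list[SignalPeptideCall]]:
    """Emit per-genome feature tables realizing a gene-content profile.

    For every true entry a feature is produced that triggers that catalog
    function and only that function; scoAB emits both subunits, and secreted
    functions (phaZ_e, phaY_e) come with secreted protein stubs in the
    returned signal-peptide calls.
    """
    catalog = catalog if catalog is not None else build_function_catalog()
    valid = {f.key for f in catalog}
    tables: dict[str, list[AnnotationFeature]] = {}
    sp_calls: list[SignalPeptideCall] = []
    for genome_id, functions in profile.items():
        feats: list[AnnotationFeature] = []
        n = 0
        for key, present in functions.items():
            if key not in valid:
                raise GeneratorError(f"unknown function key {key!r}")
            if not present:
                continue
            n += 1
            fid = f"{genome_id}.f{n}"
            if key == "scoAB":
                feats.append(AnnotationFeature(genome_id, fid + "a",
                                               "3-oxoacid CoA-transferase subunit A",
                                               ("2.8.3.5",)))
                feats.append(AnnotationFeature(genome_id, fid + "b",
                                               "3-oxoacid CoA-transferase subunit B",
                                               ("2.8.3.5",)))
                continue
            text, ec = _FEATURE_TEMPLATES[key]
            protein_id = None
            if key in ("phaZ_e", "phaZ_i", "phaY_e"):
                protein_id = f"{genome_id}.p{n}"
                secreted = key.endswith("_e")
                sp_calls.append(
                    SignalPeptideCall(protein_id=protein_id, is_secreted=secreted,
                                      cleavage_site=25 if secreted else None)
                )
            ecs = (ec,) if ec and "-" not in ec else ((ec,) if key in ("phaC", "phaG") else ())
            feats.append(
                AnnotationFeature(genome_id, fid, text, ecs, protein_id=protein_id)
            )
        tables[genome_id] = feats
    return tables, sp_calls
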