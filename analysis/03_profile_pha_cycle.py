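#!/usr/bin/env python
"""Profile the 33-genome reference gene-content matrix for PHA-cycle completeness.

Loads the packaged presence/absence matrix (consortium members and their
close relatives), derives pathway-completeness calls, and writes both tables
to results/profile/.
"""

from pathlib import Path

from phazscan.profiler import (
    call_pathways_for_matrix,
    load_reference_matrix,
    write_matrix,
    write_pathway_calls,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "profile"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ref = load_reference_matrix()
    calls = call_pathways_for_matrix(ref)
    write_matrix(ref.matrix, OUT / "gene_matrix.tsv")
    write_pathway_calls(calls, OUT / "pathway_calls.tsv")

    full = [c.genome_id for c in calls if c.full_intracellular_cycle]
    ext = [c.genome_id for c in calls if c.depoly_extracellular]
    incomplete = [c.genome_id for c in calls if not c.biosynthesis_complete]
    print(f"{len(calls)} genomes profiled")
    print(f"full intracellular PHA cycle ({len(full)}):")
    for g in full:
        print(f"  {g}")
    print(f"extracellular depolymerase/oligomer hydrolase ({len(ext)}): {', '.join(ext)}")
    print(f"biosynthesis incomplete ({len(incomplete)}): {', '.join(incomplete)}")


if __name__ == "__main__":
    main()
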