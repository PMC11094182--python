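"""Report the stability-selected core gene signature.

Reads the selection counts and core gene list written by the pipeline
run (script 02), summarizes how concentrated selection is, and checks
the core genes against the planted program.
"""

from pathlib import Path

import pandas as pd

from mutlike.io import read_gene_list

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results" / "pipeline"
SCRATCH = ROOT / "scratch" / "cohorts"


def main() -> None:
    counts = pd.read_csv(RESULTS / "signature_counts.tsv", sep="\t",
                         index_col="gene_id")["selection_count"]
    core = read_gene_list(RESULTS / "core_genes.txt")
    program = set(read_gene_list(SCRATCH / "A" / "program_genes.txt"))

    ever = counts[counts > 0].sort_values(ascending=False)
    print(f"{len(ever)} genes selected at least once across 100 elastic-net "
          f"bootstraps; top of the recurrence table:")
    print(ever.head(10).to_string())
    in_prog = sum(g in program for g in core)
    print(f"core signature: {len(core)} genes, {in_prog} inside the planted "
          f"{len(program)}-gene program")
    print("core genes:", ", ".join(core))


if __name__ == "__main__":
    main()
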