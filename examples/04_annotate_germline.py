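"""Functionality classification of a germline gene set.

Writes a simulated germline set to FASTA+TSV, loads it back through the
standard I/O path and classifies every gene with the IMGT-style rules
(coding disruptions -> pseudogene, defective signals -> ORF).
"""

import tempfile
from pathlib import Path

from trdj import (SimulationConfig, classify_functionality,
                  load_germline_set, simulate_germline, validate_rs,
                  write_germline_set)

germline, _ = simulate_germline(SimulationConfig(seed=5))

with tempfile.TemporaryDirectory() as tmp:
    fa, tsv = Path(tmp) / "genes.fa", Path(tmp) / "genes.tsv"
    write_germline_set(germline, fa, tsv)
    loaded = load_germline_set(fa, tsv)

for name in loaded.d_order + loaded.j_order:
    gene = loaded.genes[name]
    verdict, reasons = classify_functionality(gene)
    rs = gene.rs_5p or gene.rs_3p
    rs_note = ""
    if rs is not None:
        rep = validate_rs(rs)
        rs_note = (f"RS {rep.heptamer_mismatches}+{rep.nonamer_mismatches} "
                   f"mismatches ({'ok' if rep.passed else 'FAIL'})")
    print(f"{name:<7} {gene.gene_type}  {verdict:<11} "
          f"{','.join(reasons) or '-':<18} {rs_note}")

# One J gene carries a disrupted F/W-G-X-G motif and is classified as a
# pseudogene, mirroring a locus where one of four J genes never appears in
# cDNA; genes whose recombination signal drifts past the mismatch tolerance
# (1 heptamer / 2 nonamer) are downgraded to ORF.
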