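"""Germline TR gene data model, I/O and functionality classification.

A germline set holds V, D, J and C gene records for a TRA/TRD locus
together with their recombination-signal (RS) sequences and the 5'->3'
genomic order of the D and J genes.  V genes can additionally carry an
IMGT-style numbered amino-acid view (framework/CDR partition with the
conserved anchors 1st-CYS 23, CONSERVED-TRP 41, hydrophobic 89 and
2nd-CYS 104), from which functionality is classified into the IMGT
classes: functional, ORF, pseudogene or undetermined.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import AlignmentError, global_align, pairwise_identity

GENE_TYPES = {"V", "D", "J", "C"}
LOCI = {"TRA", "TRD", "shared"}
STRANDS = {"forward", "reverse"}
FUNCTIONALITY = {"functional", "ORF", "pseudogene", "undetermined"}

# Standard RS consensus (configurable; the locus literature's canonical
# heptamer/nonamer).
CONSENSUS_HEPTAMER = "CACAGTG"
CONSENSUS_NONAMER = "ACAAAAACC"

# Default spacer lengths by gene context (nt).
DEFAULT_SPACERS = {"V": 23, "D5": 12, "D3": 23, "J": 12}

# IMGT unique-numbering region spans for the V-REGION (inclusive positions).
IMGT_REGIONS = (
    ("FR1", 1, 26),
    ("CDR1", 27, 38),
    ("FR2", 39, 55),
    ("CDR2", 56, 65),
    ("FR3", 66, 104),
    ("CDR3", 105, 117),
)

HYDROPHOBIC = set("AVILMFWY")

_TSV_COLUMNS = [
    "name", "gene_type", "locus", "subgroup", "strand", "start", "end",
    "frame", "rs5_heptamer", "rs5_spacer", "rs5_nonamer",
    "rs3_heptamer", "rs3_spacer", "rs3_nonamer", "v_cdr3_len",
]


@dataclass(frozen=True)
class RSSignal:
    """One recombination signal: heptamer + 12/23-nt spacer + nonamer."""

    heptamer: str
    spacer_len: int
    nonamer: str
    heptamer_mismatches: int = 0
    nonamer_mismatches: int = 0

    def __post_init__(self):
        if len(self.heptamer) != 7:
            raise ValueError(f"heptamer must be 7 nt, got {self.heptamer!r}")
        if len(self.nonamer) != 9:
            raise ValueError(f"nonamer must be 9 nt, got {self.nonamer!r}")
        if self.spacer_len not in (12, 23):
            raise ValueError(f"spacer_len must be 12 or 23, got {self.spacer_len}")
        if self.heptamer_mismatches < 0 or self.nonamer_mismatches < 0:
            raise ValueError("mismatch counts must be non-negative")


@dataclass(frozen=True)
class RSReport:
    heptamer_mismatches: int
    nonamer_mismatches: int
    passed: bool


def validate_rs(signal: RSSignal, consensus_heptamer: str = CONSENSUS_HEPTAMER,
                consensus_nonamer: str = CONSENSUS_NONAMER,
                h_max: int = 1, n_max: int = 2) -> RSReport:
    """Hamming-compare an RS against the consensus heptamer/nonamer.

    Passes iff the heptamer has at most ``h_max`` and the nonamer at most
    ``n_max`` mismatches; signals are conserved but rarely identical.
    """
    if len(consensus_heptamer) != 7 or len(consensus_nonamer) != 9:
        raise ValueError("consensus heptamer/nonamer must be 7 and 9 nt")
    hm = sum(a != b for a, b in zip(signal.heptamer.upper(), consensus_heptamer.upper()))
    nm = sum(a != b for a, b in zip(signal.nonamer.upper(), consensus_nonamer.upper()))
    return RSReport(hm, nm, hm <= h_max and nm <= n_max)


def _imgt_labels(start: int, end: int, n: int) -> list[str]:
    """IMGT positions for n residues in the inclusive span [start, end].

    Gaps sit in the middle of the span (loop-top rule): the first
    ceil(n/2) residues take positions from the start, the rest from the
    end.  For n exceeding the span, extra residues get sub-numbered
    insertion labels after the midpoint.
    """
    width = end - start + 1
    if n <= width:
        head = (n + 1) // 2
        tail = n - head
        return ([str(p) for p in range(start, start + head)]
                + [str(p) for p in range(end - tail + 1, end + 1)])
    head = (width + 1) // 2
    anchor = start + head - 1
    extra = n - width
    labels = [str(p) for p in range(start, start + head)]
    labels += [f"{anchor}.{k}" for k in range(1, extra + 1)]
    labels += [str(p) for p in range(anchor + 1, end + 1)]
    return labels


def _label_number(label: str) -> int:
    return int(str(label).split(".")[0])


def _region_of(label: str) -> str:
    num = _label_number(label)
    for name, start, end in IMGT_REGIONS:
        if start <= num <= end:
            return name
    return "CDR3" if num > 117 else "FR1"


@dataclass(frozen=True)
class NumberedVRegion:
    """A V amino-acid sequence with IMGT-style position labels."""

    aa_seq: str
    position_labels: tuple[str, ...]

    def __post_init__(self):
        if len(self.aa_seq) != len(self.position_labels):
            raise ValueError("one label per residue required")
        nums = [_label_number(l) for l in self.position_labels]
        if any(b < a for a, b in zip(nums, nums[1:])):
            raise ValueError("labels must be non-decreasing in IMGT order")

    @classmethod
    def from_regions(cls, fr1: str, cdr1: str, fr2: str, cdr2: str,
                     fr3: str, cdr3: str = "") -> "NumberedVRegion":
        parts = dict(FR1=fr1, CDR1=cdr1, FR2=fr2, CDR2=cdr2, FR3=fr3, CDR3=cdr3)
        labels: list[str] = []
        for name, start, end in IMGT_REGIONS:
            labels.extend(_imgt_labels(start, end, len(parts[name])))
        return cls("".join(parts[name] for name, *_ in IMGT_REGIONS), tuple(labels))

    def residue_at(self, position: int) -> str | None:
        for aa, label in zip(self.aa_seq, self.position_labels):
            if label == str(position):
                return aa
        return None

    @property
    def regions(self) -> dict[str, str]:
        out = {name: "" for name, *_ in IMGT_REGIONS}
        for aa, label in zip(self.aa_seq, self.position_labels):
            out[_region_of(label)] += aa
        return out

    def region_lengths(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.regions.items()}


def number_v_region(aa_seq: str, reference: NumberedVRegion,
                    min_identity_pct: float = 30.0) -> NumberedVRegion:
    """Transfer IMGT position labels from a numbered reference by alignment.

    The query is globally aligned to the reference; matched columns
    inherit the reference label, query insertions get sub-numbered
    labels hanging off the last transferred position, and reference
    columns deleted in the query simply drop their labels.
    """
    ga, gb, _ = global_align(aa_seq, reference.aa_seq, molecule="protein")
    ident = pairwise_identity(aa_seq, reference.aa_seq, molecule="protein")
    if ident < min_identity_pct:
        raise AlignmentError(
            f"unalignable: {ident:.1f}% identity to numbering reference")
    labels: list[str] = []
    ref_i = 0
    last_anchor: str | None = None
    ins = 0
    for qc, rc in zip(ga, gb):
        if rc != "-":
            ref_label = reference.position_labels[ref_i]
            ref_i += 1
            if qc != "-":
                labels.append(ref_label)
                last_anchor, ins = ref_label, 0
        elif qc != "-":
            ins += 1
            base = _label_number(last_anchor) if last_anchor is not None else 0
            labels.append(f"{base}.{ins}")
    return NumberedVRegion(aa_seq.upper().replace("-", ""), tuple(labels))


def find_j_motif(j_aa: str) -> int | None:
    """Index of the first [FW]-G-X-G motif in a J amino-acid sequence."""
    m = re.search(r"[FW]G.G", j_aa.upper())
    return m.start() if m else None


@dataclass
class GermlineGene:
    """One germline V/D/J/C record in coding orientation."""

    name: str
    gene_type: str
    locus: str
    nt_seq: str
    strand: str = "forward"
    coords: tuple[int, int] = (0, 0)  # 0-based half-open on source scaffold
    subgroup: str | None = None
    frame: int = 0
    rs_5p: RSSignal | None = None
    rs_3p: RSSignal | None = None
    functionality: str = "undetermined"
    functionality_reasons: list[str] = field(default_factory=list)
    v_seq_kind: str | None = None     # "V-REGION" or "L-PART1+V-EXON"
    v_cdr3_len: int | None = None     # germline CDR3 length in AA
    truncated: bool = False
    splice_donor: str | None = None   # first 2 intron nt after a J, if known

    def __post_init__(self):
        self.nt_seq = self.nt_seq.upper()
        if self.gene_type not in GENE_TYPES:
            raise ValueError(f"{self.name}: invalid gene_type {self.gene_type!r}")
        if self.locus not in LOCI:
            raise ValueError(f"{self.name}: invalid locus {self.locus!r}")
        if self.strand not in STRANDS:
            raise ValueError(f"{self.name}: invalid strand {self.strand!r}")
        if self.functionality not in FUNCTIONALITY:
            raise ValueError(f"{self.name}: invalid functionality")
        n = len(self.nt_seq)
        if self.gene_type == "D" and not 1 <= n <= 64:
            raise ValueError(f"{self.name}: D-REGION length {n} outside 1..64")
        if self.gene_type == "J" and not 30 <= n <= 80:
            raise ValueError(f"{self.name}: J-REGION length {n} outside 30..80")
        if self.gene_type == "V" and not self.truncated and n < 200:
            raise ValueError(f"{self.name}: full V sequence shorter than 200 nt")
        if self.coords != (0, 0) and self.coords[1] <= self.coords[0]:
            raise ValueError(f"{self.name}: coords.end must exceed coords.start")

    @property
    def aa_seq(self) -> str:
        nt = self.nt_seq[self.frame:]
        nt = nt[: len(nt) - len(nt) % 3]
        return str(Seq(nt).translate())

    def j_frame_and_window(self) -> tuple[int, str] | None:
        """Reading frame containing the F/W-G-X-G motif, and the 5' J
        window (J-REGION start up to the codon before the motif's
        F/W 118).  None when no frame carries the motif.  The 5'-most
        motif across frames wins: in real J genes the canonical motif is
        the first one downstream of the recombination point."""
        if self.gene_type != "J":
            return None
        best = None
        for f in range(3):
            nt = self.nt_seq[f:]
            nt = nt[: len(nt) - len(nt) % 3]
            aa = str(Seq(nt).translate())
            idx = find_j_motif(aa)
            if idx is not None and (best is None or idx * 3 + f < best[0]):
                best = (idx * 3 + f, f)
        if best is None:
            return None
        window_len, frame = best
        return frame, self.nt_seq[:window_len]


@dataclass
class GermlineSet:
    """Name-indexed germline genes plus genomic D/J order."""

    genes: dict[str, GermlineGene]
    d_order: list[str] = field(default_factory=list)
    j_order: list[str] = field(default_factory=list)

    def __post_init__(self):
        for order in (self.d_order, self.j_order):
            if len(set(order)) != len(order):
                raise ValueError("order lists must not contain duplicates")
            for name in order:
                if name not in self.genes:
                    raise ValueError(f"order references unknown gene {name!r}")

    @classmethod
    def from_genes(cls, genes: list[GermlineGene]) -> "GermlineSet":
        names = [g.name for g in genes]
        if len(set(names)) != len(names):
            raise ValueError("gene names must be unique")
        by_name = {g.name: g for g in genes}

        def order_for(t: str) -> list[str]:
            sub = [g for g in genes if g.gene_type == t]
            sub.sort(key=lambda g: (g.coords[0], g.name))
            return [g.name for g in sub]

        return cls(by_name, order_for("D"), order_for("J"))

    def __len__(self) -> int:
        return len(self.genes)

    def by_type(self, gene_type: str) -> list[GermlineGene]:
        return [g for g in self.genes.values() if g.gene_type == gene_type]

    def v_window(self, name: str, default_cdr3_aa: int = 4) -> str:
        """Germline 3'V nucleotides from codon 105 to the V end."""
        gene = self.genes[name]
        aa = gene.v_cdr3_len if gene.v_cdr3_len is not None else default_cdr3_aa
        return gene.nt_seq[len(gene.nt_seq) - 3 * aa:]

    def j_windows(self) -> dict[str, str]:
        """5'J windows for every J gene whose motif frame is resolvable."""
        out = {}
        for name in self.j_order:
            fw = self.genes[name].j_frame_and_window()
            if fw is not None:
                out[name] = fw[1]
        return out


def classify_functionality(gene: GermlineGene,
                           numbered: NumberedVRegion | None = None,
                           consensus_heptamer: str = CONSENSUS_HEPTAMER,
                           consensus_nonamer: str = CONSENSUS_NONAMER,
                           h_max: int = 1, n_max: int = 2) -> tuple[str, list[str]]:
    """IMGT-style functionality verdict with the list of fired rules.

    Pseudogene: coding disruption (frameshift, in-frame stop, missing
    CYS anchors, altered J motif, broken splice donor).  ORF: coding
    intact but defective RS or a deviant non-anchor conserved residue.
    Undetermined: sequence flagged truncated.  Otherwise functional.
    """
    pseudo: list[str] = []
    orf: list[str] = []

    if gene.truncated:
        return "undetermined", ["truncated"]

    def rs_ok() -> bool:
        ok = True
        for sig in (gene.rs_5p, gene.rs_3p):
            if sig is not None:
                rep = validate_rs(sig, consensus_heptamer, consensus_nonamer,
                                  h_max, n_max)
                ok = ok and rep.passed
        return ok

    if gene.gene_type == "V":
        coding = gene.nt_seq[gene.frame:]
        if len(coding) % 3 != 0:
            pseudo.append("frameshift")
        if "*" in gene.aa_seq:
            pseudo.append("stop_codon")
        if numbered is not None:
            if numbered.residue_at(23) != "C":
                pseudo.append("missing_1st_cys")
            if numbered.residue_at(104) != "C":
                pseudo.append("missing_2nd_cys")
            if not pseudo:
                if numbered.residue_at(41) != "W":
                    orf.append("missing_conserved_trp")
                aa89 = numbered.residue_at(89)
                if aa89 is not None and aa89 not in HYDROPHOBIC:
                    orf.append("non_hydrophobic_89")
        if not rs_ok():
            orf.append("rs_defect")
    elif gene.gene_type == "J":
        if gene.j_frame_and_window() is None:
            pseudo.append("j_motif_altered")
        if gene.splice_donor is not None and gene.splice_donor.upper() != "GT":
            pseudo.append("splice_donor_defect")
        if not rs_ok():
            orf.append("rs_defect")
    elif gene.gene_type == "D":
        if not rs_ok():
            orf.append("rs_defect")
    else:  # C gene: only a stop-free reading frame is demanded
        if "*" in gene.aa_seq[:-1]:
            pseudo.append("stop_codon")

    if pseudo:
        return "pseudogene", pseudo
    if orf:
        return "ORF", orf
    return "functional", []


def _parse_rs(row: pd.Series, side: str) -> RSSignal | None:
    hept = row.get(f"rs{side}_heptamer")
    if not isinstance(hept, str) or not hept:
        return None
    return RSSignal(
        heptamer=hept,
        spacer_len=int(row[f"rs{side}_spacer"]),
        nonamer=str(row[f"rs{side}_nonamer"]),
    )


def load_germline_set(fasta_path, annotation_path) -> GermlineSet:
    """Read a germline FASTA plus its TSV annotation sidecar.

    FASTA ids must match annotation rows one-to-one.  Reverse-strand
    records are reverse-complemented into coding orientation on load.
    """
    records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}
    if not records:
        return GermlineSet({}, [], [])
    meta = pd.read_csv(annotation_path, sep="\t", dtype={"name": str},
                       keep_default_na=False, na_values=[""])
    meta_by_name = {row["name"]: row for _, row in meta.iterrows()}
    genes = []
    for name, seq in records.items():
        if name not in meta_by_name:
            raise ValueError(f"FASTA id {name!r} has no annotation row")
        row = meta_by_name[name]
        if row["strand"] == "reverse":
            seq = str(Seq(seq).reverse_complement())
        v_cdr3 = row.get("v_cdr3_len")
        genes.append(GermlineGene(
            name=name,
            gene_type=str(row["gene_type"]),
            locus=str(row["locus"]),
            nt_seq=seq,
            strand=str(row["strand"]),
            coords=(int(row["start"]), int(row["end"])),
            subgroup=(str(row["subgroup"]) if isinstance(row.get("subgroup"), str)
                      and row["subgroup"] else None),
            frame=int(row.get("frame", 0) if pd.notna(row.get("frame", 0)) else 0),
            rs_5p=_parse_rs(row, "5"),
            rs_3p=_parse_rs(row, "3"),
            v_cdr3_len=(int(v_cdr3) if pd.notna(v_cdr3) and v_cdr3 != "" else None),
        ))
    return GermlineSet.from_genes(genes)


def write_germline_set(gs: GermlineSet, fasta_path, annotation_path) -> None:
    """Inverse of :func:`load_germline_set` (coding orientation written;
    strand column set to forward accordingly)."""
    recs = []
    rows = []
    for name in sorted(gs.genes):
        g = gs.genes[name]
        recs.append(SeqRecord(Seq(g.nt_seq), id=g.name, description=""))
        rows.append({
            "name": g.name, "gene_type": g.gene_type, "locus": g.locus,
            "subgroup": g.subgroup or "", "strand": "forward",
            "start": g.coords[0], "end": g.coords[1], "frame": g.frame,
            "rs5_heptamer": g.rs_5p.heptamer if g.rs_5p else "",
            "rs5_spacer": g.rs_5p.spacer_len if g.rs_5p else "",
            "rs5_nonamer": g.rs_5p.nonamer if g.rs_5p else "",
            "rs3_heptamer": g.rs_3p.heptamer if g.rs_3p else "",
            "rs3_spacer": g.rs_3p.spacer_len if g.rs_3p else "",
            "rs3_nonamer": g.rs_3p.nonamer if g.rs_3p else "",
            "v_cdr3_len": g.v_cdr3_len if g.v_cdr3_len is not None else "",
        })
    SeqIO.write(recs, str(fasta_path), "fasta")
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(annotation_path, sep="\t", index=False)
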