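"""Synthetic germline sets and V(D)J rearrangements with ground truth.

The generator emulates how a multigene TR locus and its expressed
repertoire arise: subgroups descend from a duplicated ancestor V gene
diversified at configurable per-site divergences; rearrangements join
one V, zero to four D genes in genomic order and one J, with
exonucleolytic trimming at every joined end and non-templated N
nucleotides between every pair of joined segments, optionally filtered
for productivity (in-frame, stop-free junction).

Defaults encode the observed study conditions for a sheep-like TRD
repertoire: seven D genes of 9-15 nt, four J genes with one pseudogene,
a D-count split of roughly 11/23/37/27/2 %, geometric trimming with
mean 4.09 nt at the 3'V and 2.12 nt at the 5'J, and Poisson(3) N-region
lengths (the N-length law is a modelling stand-in, not an observation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

import pandas as pd

from .germline import (CONSENSUS_HEPTAMER, CONSENSUS_NONAMER, DEFAULT_SPACERS,
                       GermlineGene, GermlineSet, RSSignal)
from .junction import DHit, JunctionDecomposition, check_productivity

NT = np.array(list("ACGT"))
STOPS = {"TAA", "TAG", "TGA"}
_TISSUE_CYCLE = ("thymus", "spleen", "blood", "uterus")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    # germline architecture
    n_v_subgroups: int = 4
    genes_per_subgroup: int = 3
    alleles_per_gene: int = 1
    v_len: int = 300
    v_cdr3_aa: int = 4
    subgroup_divergence: float = 0.35
    within_subgroup_divergence: float = 0.10
    allele_divergence: float = 0.01
    n_d: int = 7
    d_lens: tuple[int, ...] | None = (9, 11, 11, 12, 13, 13, 15)
    d_len_range: tuple[int, int] = (9, 15)
    n_j: int = 4
    j_window_range: tuple[int, int] = (15, 21)
    j_pseudogene_index: int | None = 2
    # rearrangement process
    chain: str = "TRD"
    d_count_dist: tuple[float, ...] = (0.11, 0.23, 0.37, 0.27, 0.02)
    v_trim_mean: float = 4.09
    j_trim_mean: float = 2.12
    d_trim_mean: float = 1.0
    v_trim_cap: int = 25
    n_len_mean: float = 3.0
    productivity_filter: bool = True

    def __post_init__(self):
        if abs(sum(self.d_count_dist) - 1.0) > 1e-9:
            raise ValueError("d_count_dist probabilities must sum to 1")
        for p in (self.subgroup_divergence, self.within_subgroup_divergence,
                  self.allele_divergence):
            if not 0.0 <= p <= 1.0:
                raise ValueError("divergences must lie in [0, 1]")
        if self.d_lens is not None:
            if len(self.d_lens) != self.n_d:
                raise ValueError("d_lens must list one length per D gene")
            if any(not 1 <= l <= 64 for l in self.d_lens):
                raise ValueError("D lengths must lie in 1..64")


@dataclass(frozen=True)
class GermlineTruth:
    """Generative labels: which subgroup and which gene each V came from."""

    subgroup_of: dict[str, str]
    gene_of: dict[str, str]


@dataclass
class SyntheticClone:
    clone_id: str
    tissue: str
    chain: str
    junction: str
    truth: JunctionDecomposition
    draws: dict = field(default_factory=dict)


def _geometric0(rng: np.random.Generator, mean: float, size=None):
    """Geometric on {0,1,2,...} with the given mean."""
    if mean <= 0:
        return np.zeros(size, dtype=int) if size else 0
    p = 1.0 / (1.0 + mean)
    return rng.geometric(p, size=size) - 1


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(NT, size=n)) if n > 0 else ""


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = np.array(list(seq))
    hit = rng.random(len(chars)) < rate
    for i in np.flatnonzero(hit):
        options = [b for b in "ACGT" if b != chars[i]]
        chars[i] = options[rng.integers(3)]
    return "".join(chars)


def _random_rs(rng: np.random.Generator, spacer_len: int) -> RSSignal:
    hept = list(CONSENSUS_HEPTAMER)
    nona = list(CONSENSUS_NONAMER)
    if rng.random() < 0.5:  # sampled mismatches: signals conserved, not identical
        i = rng.integers(7)
        hept[i] = [b for b in "ACGT" if b != hept[i]][rng.integers(3)]
    for _ in range(int(rng.integers(0, 3))):
        i = rng.integers(9)
        nona[i] = [b for b in "ACGT" if b != nona[i]][rng.integers(3)]
    return RSSignal("".join(hept), spacer_len, "".join(nona))


def _stop_free_codons(rng: np.random.Generator, n_codons: int) -> str:
    out = []
    while len(out) < n_codons:
        codon = _random_nt(rng, 3)
        if codon not in STOPS:
            out.append(codon)
    return "".join(out)


def _make_j(rng: np.random.Generator, cfg: SimulationConfig,
            pseudo: bool) -> tuple[str, str]:
    """One J gene; returns (nt_seq, intended 5' window).  The F/W-G-X-G
    motif sits right after the window; pseudogenes get it disrupted."""
    for _ in range(200):
        w = int(rng.integers(cfg.j_window_range[0], cfg.j_window_range[1] + 1))
        window = _random_nt(rng, w)
        motif = ("TTT" if rng.random() < 0.7 else "TGG") + "GGA" \
            + _stop_free_codons(rng, 1) + "GGT"
        tail = _stop_free_codons(rng, 7)
        seq = window + motif + tail
        if pseudo:
            seq = window + "CTT" + motif[3:] + tail  # F/W -> L kills the motif
            gene = GermlineGene(name="tmp", gene_type="J", locus="TRD", nt_seq=seq)
            if gene.j_frame_and_window() is None:
                return seq, window
            continue
        gene = GermlineGene(name="tmp", gene_type="J", locus="TRD", nt_seq=seq)
        fw = gene.j_frame_and_window()
        if fw is not None and fw[1] == window:
            return seq, window
    raise RuntimeError("could not generate a clean J gene")


def simulate_germline(config: SimulationConfig) -> tuple[GermlineSet, GermlineTruth]:
    """Duplication+mutation germline set with generative truth labels.

    Each subgroup descends from an independently drawn subgroup ancestor
    (after mutating a shared root at ``subgroup_divergence``); members
    diverge at ``within_subgroup_divergence`` and alleles at
    ``allele_divergence``.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    genes: list[GermlineGene] = []
    subgroup_of: dict[str, str] = {}
    gene_of: dict[str, str] = {}

    root = _random_nt(rng, config.v_len)
    pos = 1000
    for s in range(1, config.n_v_subgroups + 1):
        ancestor = _mutate(rng, root, config.subgroup_divergence)
        sg_label = f"SIMV{s}"
        for m in range(1, config.genes_per_subgroup + 1):
            member = _mutate(rng, ancestor, config.within_subgroup_divergence)
            gene_label = f"SIMV{s}S{m}"
            for a in range(1, config.alleles_per_gene + 1):
                seq = member if a == 1 else _mutate(rng, member,
                                                   config.allele_divergence)
                name = gene_label if config.alleles_per_gene == 1 \
                    else f"{gene_label}a{a}"
                genes.append(GermlineGene(
                    name=name, gene_type="V", locus="TRD", nt_seq=seq,
                    coords=(pos, pos + config.v_len), subgroup=sg_label,
                    v_seq_kind="V-REGION", v_cdr3_len=config.v_cdr3_aa,
                    rs_3p=_random_rs(rng, DEFAULT_SPACERS["V"])))
                subgroup_of[name] = sg_label
                gene_of[name] = gene_label
                pos += 2000

    d_lens = (list(config.d_lens) if config.d_lens is not None
              else list(rng.integers(config.d_len_range[0],
                                     config.d_len_range[1] + 1, config.n_d)))
    for i, dlen in enumerate(d_lens, start=1):
        genes.append(GermlineGene(
            name=f"SIMD{i}", gene_type="D", locus="TRD",
            nt_seq=_random_nt(rng, int(dlen)), coords=(pos, pos + int(dlen)),
            rs_5p=_random_rs(rng, DEFAULT_SPACERS["D5"]),
            rs_3p=_random_rs(rng, DEFAULT_SPACERS["D3"])))
        pos += 500

    for i in range(1, config.n_j + 1):
        pseudo = config.j_pseudogene_index is not None \
            and i - 1 == config.j_pseudogene_index
        seq, _ = _make_j(rng, config, pseudo)
        genes.append(GermlineGene(
            name=f"SIMJ{i}", gene_type="J", locus="TRD", nt_seq=seq,
            coords=(pos, pos + len(seq)),
            rs_5p=_random_rs(rng, DEFAULT_SPACERS["J"]),
            splice_donor="GT"))
        pos += 300

    genes.append(GermlineGene(
        name="SIMC", gene_type="C", locus="TRD",
        nt_seq=_stop_free_codons(rng, 90), coords=(pos, pos + 270)))

    return GermlineSet.from_genes(genes), GermlineTruth(subgroup_of, gene_of)


def _build_clone(rng: np.random.Generator, germline: GermlineSet,
                 cfg: SimulationConfig, clone_id: str, tissue: str
                 ) -> SyntheticClone:
    v_names = sorted(g.name for g in germline.by_type("V"))
    j_windows = germline.j_windows()
    if not v_names or not j_windows:
        raise ValueError("germline set needs V genes and functional J genes")

    v_name = v_names[rng.integers(len(v_names))]
    v_window = germline.v_window(v_name)
    k = 0
    if cfg.chain == "TRD":
        k = int(rng.choice(len(cfg.d_count_dist), p=cfg.d_count_dist))
        k = min(k, len(germline.d_order))
    d_names = ([germline.d_order[i]
                for i in sorted(rng.choice(len(germline.d_order), size=k,
                                           replace=False))]
               if k else [])
    j_names = sorted(j_windows)
    j_name = j_names[rng.integers(len(j_names))]
    j_window = j_windows[j_name]

    v_trim_raw = int(min(_geometric0(rng, cfg.v_trim_mean), cfg.v_trim_cap))
    v_contrib = v_window[:max(0, len(v_window) - v_trim_raw)]
    j_trim = int(min(_geometric0(rng, cfg.j_trim_mean), len(j_window)))
    j_contrib = j_window[j_trim:]

    d_parts: list[tuple[str, str, tuple[int, int], tuple[int, int]]] = []
    d_trims: list[tuple[int, int]] = []
    for name in d_names:
        d_seq = germline.genes[name].nt_seq
        t5 = int(min(_geometric0(rng, cfg.d_trim_mean), len(d_seq)))
        t3 = int(min(_geometric0(rng, cfg.d_trim_mean), len(d_seq) - t5))
        d_trims.append((t5, t3))
        remnant = d_seq[t5: len(d_seq) - t3]
        if remnant:
            d_parts.append((name, remnant, (t5, len(d_seq) - t3), (t5, t3)))

    n_lens = [int(rng.poisson(cfg.n_len_mean)) for _ in range(len(d_parts) + 1)]
    n_seqs = [_random_nt(rng, n) for n in n_lens]

    pieces = [v_contrib]
    d_hits: list[DHit] = []
    cursor = len(v_contrib)
    for (name, remnant, germ_iv, _), nseq in zip(d_parts, n_seqs[:-1]):
        pieces.append(nseq)
        cursor += len(nseq)
        d_hits.append(DHit(name, (cursor, cursor + len(remnant)), germ_iv))
        pieces.append(remnant)
        cursor += len(remnant)
    pieces.append(n_seqs[-1])
    pieces.append(j_contrib)
    junction = "".join(pieces)

    truth = JunctionDecomposition(
        clone_id=clone_id, chain=cfg.chain, junction=junction,
        v_name=v_name, v_contrib_len=len(v_contrib),
        v_trim=len(v_window) - len(v_contrib),
        d_hits=d_hits, n_regions=n_lens,
        j_name=j_name, j_contrib_len=len(j_contrib), j_trim=j_trim,
        productive=check_productivity(junction), tissue=tissue,
        v_subgroup=germline.genes[v_name].subgroup)
    assert truth.check_partition()
    return SyntheticClone(clone_id, tissue, cfg.chain, junction, truth,
                          draws={"v_trim_raw": v_trim_raw, "j_trim": j_trim,
                                 "d_count": k, "d_names": d_names,
                                 "d_trims": d_trims, "n_lens": n_lens})


def simulate_rearrangement(germline: GermlineSet, config: SimulationConfig,
                           n: int) -> list[SyntheticClone]:
    """Simulate ``n`` clones; with the productivity filter on, each clone
    is resampled (up to 1,000 attempts) until in-frame and stop-free."""
    rng = np.random.default_rng((config.seed + 10007) % (2 ** 31))
    clones = []
    for i in range(n):
        tissue = _TISSUE_CYCLE[i % len(_TISSUE_CYCLE)]
        clone_id = f"SIMCL{i + 1:05d}"
        for attempt in range(1000):
            clone = _build_clone(rng, germline, config, clone_id, tissue)
            if not clone.junction:
                continue  # degenerate draw: everything trimmed away
            if not config.productivity_filter or clone.truth.productive:
                break
        else:
            raise RuntimeError(
                f"productivity filter exhausted 1000 attempts (config {config})")
        clones.append(clone)
    return clones


def write_clone_set(clones: list[SyntheticClone], fasta_path, truth_path) -> None:
    """FASTA of junctions plus a TSV of ground-truth decompositions."""
    recs = [SeqRecord(Seq(c.junction), id=c.clone_id,
                      description=f"{c.chain} {c.tissue}") for c in clones]
    SeqIO.write(recs, str(fasta_path), "fasta")
    rows = []
    for c in clones:
        t = c.truth
        rows.append({
            "clone_id": c.clone_id, "tissue": c.tissue, "chain": c.chain,
            "junction": c.junction, "v_name": t.v_name,
            "v_contrib_len": t.v_contrib_len, "v_trim": t.v_trim,
            "v_subgroup": t.v_subgroup or "",
            "d_hits": json.dumps([[h.d_name, list(h.junction_interval),
                                   list(h.germline_interval)] for h in t.d_hits]),
            "n_regions": json.dumps(t.n_regions),
            "j_name": t.j_name, "j_contrib_len": t.j_contrib_len,
            "j_trim": t.j_trim, "productive": t.productive,
            "draws": json.dumps(c.draws),
        })
    pd.DataFrame(rows).to_csv(truth_path, sep="\t", index=False)


def read_clone_set(fasta_path, truth_path) -> list[SyntheticClone]:
    seqs = {r.id: (str(r.seq), r.description) for r in
            SeqIO.parse(str(fasta_path), "fasta")}
    meta = pd.read_csv(truth_path, sep="\t", keep_default_na=False)
    clones = []
    for _, row in meta.iterrows():
        junction, _ = seqs[row["clone_id"]]
        d_hits = [DHit(name, tuple(jiv), tuple(giv))
                  for name, jiv, giv in json.loads(row["d_hits"])]
        truth = JunctionDecomposition(
            clone_id=row["clone_id"], chain=row["chain"], junction=junction,
            v_name=row["v_name"], v_contrib_len=int(row["v_contrib_len"]),
            v_trim=int(row["v_trim"]), d_hits=d_hits,
            n_regions=json.loads(row["n_regions"]),
            j_name=row["j_name"], j_contrib_len=int(row["j_contrib_len"]),
            j_trim=int(row["j_trim"]),
            productive=bool(row["productive"] in (True, "True", "true", 1)),
            tissue=row["tissue"],
            v_subgroup=row["v_subgroup"] or None)
        clones.append(SyntheticClone(row["clone_id"], row["tissue"],
                                     row["chain"], junction, truth,
                                     json.loads(row["draws"])))
    return clones
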