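"""Repertoire summary statistics over junction decompositions.

Conventions mirror the usual repertoire-report bookkeeping for a small
clone panel: D-gene usage counts clones containing at least one stretch
of that D (not stretch multiplicity) over the denominator of clones
with any recognisable D; J and V usage are over all clones.  CDR3
lengths are amino acids (junction nt / 3) on productive clones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

from .junction import JunctionDecomposition

_TISSUE_ALIASES = {
    "thymus": "thymus", "perinatal thymus": "thymus",
    "spleen": "spleen",
    "blood": "blood", "peripheral blood": "blood", "pbmc": "blood",
    "uterus": "uterus", "pregnant uterus": "uterus",
}


def normalize_tissue(label: str | None) -> str:
    if label is None:
        return "other"
    return _TISSUE_ALIASES.get(label.strip().lower(), "other")


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _length_stats(values: list[int | float]) -> dict:
    if not values:
        return {"n": 0, "mean": None, "min": None, "max": None}
    return {"n": len(values), "mean": sum(values) / len(values),
            "min": min(values), "max": max(values)}


@dataclass
class RepertoireSummary:
    n_clones: int
    usage: dict[str, dict[str, dict]]          # gene_type -> gene -> {count, denominator}
    cdr3_stats: dict[str, dict]                # "overall" plus group keys
    trim_stats: dict[str, dict]                # v_trim / j_trim
    d_count_histogram: dict[str, int]          # "0".."3", "4+"
    groups: dict[str, dict[str, dict]] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "n_clones": self.n_clones,
            "usage": self.usage,
            "cdr3_stats": self.cdr3_stats,
            "trim_stats": self.trim_stats,
            "d_count_histogram": self.d_count_histogram,
            "groups": self.groups,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RepertoireSummary":
        d = json.loads(text)
        return cls(d["n_clones"], d["usage"], d["cdr3_stats"],
                   d["trim_stats"], d["d_count_histogram"], d.get("groups", {}))


def _d_bucket(d_count: int) -> str:
    return str(d_count) if d_count < 4 else "4+"


def summarize(decomps: list[JunctionDecomposition],
              group_by: set[str] = frozenset()) -> RepertoireSummary:
    """Aggregate decompositions into usage, CDR3-length and trim statistics.

    ``group_by`` may contain ``tissue``, ``d_count`` and ``v_subgroup``;
    each requested axis adds per-group CDR3-length statistics.
    """
    if not decomps:
        raise ValueError("no decompositions to summarize")
    bad = set(group_by) - {"tissue", "d_count", "v_subgroup"}
    if bad:
        raise ValueError(f"unknown grouping axes: {sorted(bad)}")

    n = len(decomps)
    with_d = [d for d in decomps if d.d_count > 0]

    usage: dict[str, dict[str, dict]] = {"V": {}, "D": {}, "J": {}}
    for d in decomps:
        usage["V"].setdefault(d.v_name, {"count": 0, "denominator": n})["count"] += 1
        if d.j_name is not None:
            usage["J"].setdefault(d.j_name, {"count": 0, "denominator": n})["count"] += 1
        for name in sorted({h.d_name for h in d.d_hits}):
            usage["D"].setdefault(name, {"count": 0,
                                         "denominator": len(with_d)})["count"] += 1

    lengths = [d.cdr3_aa_len for d in decomps if d.cdr3_aa_len is not None]
    cdr3_stats = {"overall": _length_stats(lengths)}

    groups: dict[str, dict[str, dict]] = {}
    keyers = {
        "tissue": lambda d: normalize_tissue(d.tissue),
        "d_count": lambda d: _d_bucket(d.d_count),
        "v_subgroup": lambda d: d.v_subgroup or "unassigned",
    }
    for axis in sorted(group_by):
        keyer = keyers[axis]
        by: dict[str, list] = {}
        for d in decomps:
            if d.cdr3_aa_len is not None:
                by.setdefault(keyer(d), []).append(d.cdr3_aa_len)
        groups[axis] = {k: _length_stats(v) for k, v in sorted(by.items())}

    trim_stats = {
        "v_trim": _length_stats([d.v_trim for d in decomps]),
        "j_trim": _length_stats([d.j_trim for d in decomps]),
    }
    hist = {b: 0 for b in ("0", "1", "2", "3", "4+")}
    for d in decomps:
        hist[_d_bucket(d.d_count)] += 1

    return RepertoireSummary(n, usage, cdr3_stats, trim_stats, hist, groups)


def usage_table(decomps: list[JunctionDecomposition],
                gene_type: str) -> pd.DataFrame:
    """Per-gene clone counts with denominators, as a tidy table."""
    if gene_type not in {"V", "D", "J"}:
        raise ValueError("gene_type must be V, D or J")
    summary = summarize(decomps)
    rows = [{"gene": g, "count": rec["count"], "denominator": rec["denominator"]}
            for g, rec in sorted(summary.usage[gene_type].items())]
    return pd.DataFrame(rows, columns=["gene", "count", "denominator"])


def positional_bias(decomps: list[JunctionDecomposition], j_order: list[str],
                    boundary: int | None = None) -> dict[str, int]:
    """J usage split at an order boundary (proximal = first ``boundary``
    genes of ``j_order``; default midpoint)."""
    if boundary is None:
        boundary = len(j_order) // 2
    proximal = set(j_order[:boundary])
    distal = set(j_order[boundary:])
    counts = {"proximal": 0, "distal": 0}
    for d in decomps:
        if d.j_name is None:
            continue
        if d.j_name in proximal:
            counts["proximal"] += 1
        elif d.j_name in distal:
            counts["distal"] += 1
        else:
            raise ValueError(f"J gene {d.j_name!r} not in j_order")
    return counts


def export_report(summary: RepertoireSummary, path, fmt: str = "json",
                  germline_order: list[str] | None = None) -> None:
    """Write a summary as lossless JSON, TSV or a markdown report.

    Text formats round means to 2 decimals (half-up); JSON is unrounded.
    """
    path = str(path)
    if fmt == "json":
        with open(path, "w") as fh:
            fh.write(summary.to_json())
        return
    rows = []
    for gene_type in ("V", "D", "J"):
        genes = summary.usage[gene_type]
        order = [g for g in (germline_order or []) if g in genes]
        order += [g for g in sorted(genes) if g not in order]
        for g in order:
            rec = genes[g]
            rows.append((gene_type, g, rec["count"], rec["denominator"]))
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("section\tkey\tvalue\tdenominator_or_extra\n")
            fh.write(f"clones\tn_clones\t{summary.n_clones}\t\n")
            for gene_type, g, c, denom in rows:
                fh.write(f"usage_{gene_type}\t{g}\t{c}\t{denom}\n")
            ov = summary.cdr3_stats["overall"]
            fh.write(f"cdr3\tmean_aa\t{_round2(ov['mean'])}\t\n")
            fh.write(f"cdr3\trange_aa\t{ov['min']}-{ov['max']}\t\n")
            for which in ("v_trim", "j_trim"):
                st = summary.trim_stats[which]
                fh.write(f"trim\t{which}_mean\t{_round2(st['mean'])}\t\n")
            for bucket, count in summary.d_count_histogram.items():
                fh.write(f"d_count\t{bucket}\t{count}\t\n")
    elif fmt == "markdown":
        lines = ["# Repertoire summary", "",
                 f"Clones analysed: {summary.n_clones}", "",
                 "| type | gene | clones | denominator |",
                 "|------|------|--------|-------------|"]
        lines += [f"| {t} | {g} | {c} | {dnm} |" for t, g, c, dnm in rows]
        ov = summary.cdr3_stats["overall"]
        lines += ["", f"Mean CDR3 length: {_round2(ov['mean'])} AA "
                      f"(range {ov['min']}-{ov['max']} AA)"]
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def load_report(path) -> RepertoireSummary:
    with open(str(path)) as fh:
        return RepertoireSummary.from_json(fh.read())
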