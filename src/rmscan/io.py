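"""Readers and writers for annotations, sequences and summary reports.

Two annotation dialects are supported and round-trip losslessly:

* ``rebase_tsv`` — a tab-separated table with header columns
  ``genome_id replicon_id gene_id start end strand role rm_type corrupted
  system_id product`` (coordinates 0-based half-open) preceded by replicon
  declaration pragmas ``##replicon <genome_id> <replicon_id> <length>
  <topology>``.  A gene spanning the origin of a circular replicon is written
  as one row per arc, sharing the gene_id; the reader merges such rows.

* ``gff3`` — standard GFF3 ``gene`` rows with 1-based inclusive coordinates,
  converted to the internal 0-based half-open convention on read.  Replicon
  lengths come from ``##sequence-region`` pragmas; genome membership and
  circular topology from ``#!genome`` / ``#!topology`` pragmas.

Protein sequences travel separately as FASTA keyed by gene_id.
"""

from __future__ import annotations

import json
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import GeneRecord, Replicon, Role, RMType, Topology, ValidationError

__all__ = [
    "ParseError",
    "read_annotation",
    "write_annotation",
    "read_fasta",
    "write_fasta",
    "attach_proteins",
    "write_report",
    "REPORT_SCHEMA_VERSION",
]

TSV_COLUMNS = (
    "genome_id",
    "replicon_id",
    "gene_id",
    "start",
    "end",
    "strand",
    "role",
    "rm_type",
    "corrupted",
    "system_id",
    "product",
)

REPORT_SCHEMA_VERSION = "1.0"


class ParseError(ValueError):
    """Malformed input; the message names the offending file line."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> Dict[str, str]:
    """Read a FASTA file into an id -> sequence dict (ids must be unique)."""
    out: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ParseError(f"{path}: duplicate FASTA id {rec.id!r}")
        out[rec.id] = str(rec.seq)
    return out


def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def attach_proteins(genes: Sequence[GeneRecord], proteins: Mapping[str, str]) -> List[GeneRecord]:
    """Return genes with protein sequences filled in from a gene_id-keyed table."""
    out = []
    for g in genes:
        if g.protein_seq is None and g.gene_id in proteins:
            out.append(g.with_protein(proteins[g.gene_id]))
        else:
            out.append(g)
    return out


# ---------------------------------------------------------------------------
# annotation dialects
# ---------------------------------------------------------------------------

def read_annotation(path, dialect: str = "rebase_tsv") -> Tuple[List[GeneRecord], List[Replicon]]:
    """Parse an annotation file into gene records and replicons.

    Unknown roles / R-M types map to ``other`` / ``unknown``.  A gene row
    referencing an undeclared replicon, or with malformed coordinates, raises
    :class:`ParseError` naming the line.
    """
    if dialect == "rebase_tsv":
        return _read_tsv(path)
    if dialect == "gff3":
        return _read_gff3(path)
    raise ValidationError(f"unknown annotation dialect {dialect!r}")


def write_annotation(
    genes: Sequence[GeneRecord],
    replicons: Sequence[Replicon],
    path,
    dialect: str = "rebase_tsv",
) -> None:
    if dialect == "rebase_tsv":
        _write_tsv(genes, replicons, path)
    elif dialect == "gff3":
        _write_gff3(genes, replicons, path)
    else:
        raise ValidationError(f"unknown annotation dialect {dialect!r}")


def _parse_coord(text: str, path, lineno: int) -> int:
    try:
        return int(text)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: malformed coordinate {text!r}") from None


def _read_tsv(path) -> Tuple[List[GeneRecord], List[Replicon]]:
    replicons: Dict[str, Replicon] = {}
    rows: List[dict] = []
    header: Optional[List[str]] = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("##replicon"):
                parts = line.split("\t")
                if len(parts) != 5:
                    raise ParseError(f"{path}:{lineno}: ##replicon pragma needs 4 fields")
                _, genome_id, rep_id, length, topo = parts
                replicons[rep_id] = Replicon(
                    id=rep_id,
                    genome_id=genome_id,
                    length=_parse_coord(length, path, lineno),
                    topology=Topology(topo),
                )
                continue
            if line.startswith("#"):
                if header is None and "gene_id" in line:
                    header = line.lstrip("#").split("\t")
                continue
            parts = line.split("\t")
            if header is None:
                header = list(TSV_COLUMNS)
            if len(parts) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} columns, found {len(parts)}"
                )
            row = dict(zip(header, parts))
            row["_lineno"] = lineno
            rows.append(row)

    # merge multi-arc rows (same gene_id) into single records
    genes: List[GeneRecord] = []
    pending: Dict[str, dict] = {}
    order: List[str] = []
    for row in rows:
        gid = row["gene_id"]
        lineno = row["_lineno"]
        rep_id = row["replicon_id"]
        if rep_id not in replicons:
            raise ParseError(f"{path}:{lineno}: gene {gid!r} references unknown replicon {rep_id!r}")
        start = _parse_coord(row["start"], path, lineno)
        end = _parse_coord(row["end"], path, lineno)
        if not (0 <= start < end <= replicons[rep_id].length):
            raise ParseError(
                f"{path}:{lineno}: malformed coordinates [{start}, {end}) for gene {gid!r}"
            )
        if gid in pending:
            prev = pending[gid]
            if prev["replicon_id"] != rep_id:
                raise ParseError(f"{path}:{lineno}: arcs of gene {gid!r} on different replicons")
            prev["arcs"].append((start, end))
        else:
            row["arcs"] = [(start, end)]
            pending[gid] = row
            order.append(gid)
    for gid in order:
        row = pending[gid]
        arcs = tuple(row["arcs"])
        genes.append(
            GeneRecord(
                gene_id=gid,
                genome_id=row["genome_id"],
                replicon_id=row["replicon_id"],
                start=arcs[0][0],
                end=arcs[-1][1],
                strand=row["strand"],
                role=Role.parse(row["role"]),
                rm_type=RMType.parse(row["rm_type"]),
                corrupted=row["corrupted"].strip().lower() in ("1", "true", "yes"),
                system_id=row.get("system_id") or None,
                product=row.get("product") or None,
                arcs=arcs if len(arcs) > 1 else None,
            )
        )
    return genes, sorted(replicons.values(), key=lambda r: r.id)


def _write_tsv(genes: Sequence[GeneRecord], replicons: Sequence[Replicon], path) -> None:
    with open(path, "w") as fh:
        for rep in sorted(replicons, key=lambda r: r.id):
            fh.write(
                f"##replicon\t{rep.genome_id}\t{rep.id}\t{rep.length}\t{rep.topology.value}\n"
            )
        fh.write("#" + "\t".join(TSV_COLUMNS) + "\n")
        for g in genes:
            for s, e in g.intervals:
                fh.write(
                    "\t".join(
                        [
                            g.genome_id,
                            g.replicon_id,
                            g.gene_id,
                            str(s),
                            str(e),
                            g.strand,
                            g.role.value,
                            g.rm_type.value,
                            "true" if g.corrupted else "false",
                            g.system_id or "",
                            g.product or "",
                        ]
                    )
                    + "\n"
                )


def _gff3_escape(text: str) -> str:
    return text.replace("%", "%25").replace(";", "%3B").replace("=", "%3D").replace(",", "%2C")


def _gff3_unescape(text: str) -> str:
    return (
        text.replace("%2C", ",").replace("%3D", "=").replace("%3B", ";").replace("%25", "%")
    )


def _read_gff3(path) -> Tuple[List[GeneRecord], List[Replicon]]:
    lengths: Dict[str, int] = {}
    genomes: Dict[str, str] = {}
    topologies: Dict[str, Topology] = {}
    raw_genes: Dict[str, dict] = {}
    order: List[str] = []
    with open(path) as fh:
        for lineno, rawline in enumerate(fh, 1):
            line = rawline.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) != 4:
                    raise ParseError(f"{path}:{lineno}: malformed ##sequence-region")
                lengths[parts[1]] = _parse_coord(parts[3], path, lineno)
                continue
            if line.startswith("#!genome"):
                _, rep_id, genome_id = line.split()
                genomes[rep_id] = genome_id
                continue
            if line.startswith("#!topology"):
                _, rep_id, topo = line.split()
                topologies[rep_id] = Topology(topo)
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: GFF3 rows need 9 columns")
            seqid, _source, _ftype, start1, end1, _score, strand, _phase, attr_text = cols
            if seqid not in lengths:
                raise ParseError(f"{path}:{lineno}: row references unknown replicon {seqid!r}")
            # GFF3 is 1-based inclusive; internal convention is 0-based half-open
            start = _parse_coord(start1, path, lineno) - 1
            end = _parse_coord(end1, path, lineno)
            if not (0 <= start < end <= lengths[seqid]):
                raise ParseError(f"{path}:{lineno}: malformed coordinates {start1}..{end1}")
            attrs = {}
            for chunk in attr_text.split(";"):
                if not chunk:
                    continue
                if "=" not in chunk:
                    raise ParseError(f"{path}:{lineno}: malformed attribute {chunk!r}")
                k, v = chunk.split("=", 1)
                attrs[k] = _gff3_unescape(v)
            gid = attrs.get("ID")
            if gid is None:
                raise ParseError(f"{path}:{lineno}: gene row without ID attribute")
            if gid in raw_genes:
                prev = raw_genes[gid]
                if prev["seqid"] != seqid:
                    raise ParseError(f"{path}:{lineno}: arcs of gene {gid!r} on different replicons")
                prev["arcs"].append((start, end))
            else:
                raw_genes[gid] = {
                    "seqid": seqid,
                    "arcs": [(start, end)],
                    "strand": strand if strand in "+-" else "+",
                    "attrs": attrs,
                }
                order.append(gid)

    replicons = [
        Replicon(
            id=rep_id,
            genome_id=genomes.get(rep_id, rep_id),
            length=length,
            topology=topologies.get(rep_id, Topology.LINEAR),
        )
        for rep_id, length in sorted(lengths.items())
    ]
    genes: List[GeneRecord] = []
    for gid in order:
        raw = raw_genes[gid]
        attrs = raw["attrs"]
        arcs = tuple(raw["arcs"])
        genes.append(
            GeneRecord(
                gene_id=gid,
                genome_id=attrs.get("genome_id", genomes.get(raw["seqid"], raw["seqid"])),
                replicon_id=raw["seqid"],
                start=arcs[0][0],
                end=arcs[-1][1],
                strand=raw["strand"],
                role=Role.parse(attrs.get("role", "other")),
                rm_type=RMType.parse(attrs.get("rm_type", "unknown")),
                corrupted=attrs.get("corrupted", "false").lower() in ("1", "true", "yes"),
                system_id=attrs.get("system_id") or None,
                product=attrs.get("product") or None,
                arcs=arcs if len(arcs) > 1 else None,
            )
        )
    return genes, replicons


def _write_gff3(genes: Sequence[GeneRecord], replicons: Sequence[Replicon], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rep in sorted(replicons, key=lambda r: r.id):
            fh.write(f"##sequence-region {rep.id} 1 {rep.length}\n")
            fh.write(f"#!genome {rep.id} {rep.genome_id}\n")
            fh.write(f"#!topology {rep.id} {rep.topology.value}\n")
        for g in genes:
            attrs = [f"ID={_gff3_escape(g.gene_id)}", f"genome_id={_gff3_escape(g.genome_id)}"]
            attrs.append(f"role={g.role.value}")
            attrs.append(f"rm_type={g.rm_type.value}")
            attrs.append(f"corrupted={'true' if g.corrupted else 'false'}")
            if g.system_id:
                attrs.append(f"system_id={_gff3_escape(g.system_id)}")
            if g.product:
                attrs.append(f"product={_gff3_escape(g.product)}")
            for s, e in g.intervals:
                fh.write(
                    "\t".join(
                        [
                            g.replicon_id,
                            "rmscan",
                            "gene",
                            str(s + 1),  # back to 1-based inclusive
                            str(e),
                            ".",
                            g.strand,
                            ".",
                            ";".join(attrs),
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# classification summary reports
# ---------------------------------------------------------------------------

CLASS_ORDER = (
    "probably_truncated",
    "separated_system_member",
    "corrupted_mtase_nearby",
    "no_paired_mtase",
    "no_orthologs",
)


def summary_counts(classifications) -> dict:
    """Per-R-M-type class counts plus row/column totals, in a fixed key order."""
    types = sorted({c.re_gene.rm_type.value for c in classifications})
    table = {t: {cls: 0 for cls in CLASS_ORDER} for t in types}
    for c in classifications:
        table[c.re_gene.rm_type.value][c.verdict] += 1
    rows = []
    for t in types:
        row = {"rm_type": t}
        row.update(table[t])
        row["total"] = sum(table[t].values())
        rows.append(row)
    totals = {cls: sum(table[t][cls] for t in types) for cls in CLASS_ORDER}
    totals_row = {"rm_type": "total"}
    totals_row.update(totals)
    totals_row["total"] = sum(totals.values())
    return {"schema_version": REPORT_SCHEMA_VERSION, "rows": rows, "totals": totals_row}


def write_report(classifications, path, fmt: str = "json") -> dict:
    """Write the per-type classification summary; returns the summary dict.

    JSON and TSV renderings are generated from the same counts, so they agree
    by construction.
    """
    summary = summary_counts(classifications)
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif fmt == "tsv":
        cols = ("rm_type",) + CLASS_ORDER + ("total",)
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for row in summary["rows"] + [summary["totals"]]:
                fh.write("\t".join(str(row[c]) for c in cols) + "\n")
    else:
        raise ValidationError(f"unknown report format {fmt!r}")
    return summary
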