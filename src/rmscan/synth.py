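"""Synthetic genome cohorts with planted R-M scenarios and ground-truth labels.

Cohort generation is a pure function of (spec, seed).  Protein families are
derived from a random root by i.i.d. substitutions, uniform over the 19
alternative residues (no rate matrix — enough to exercise the identity
thresholds, and deliberately non-biological).  Proteins are reverse
translated with a fixed codon per residue so the six-frame ORF scan can
re-find them; intergenic sequence is random nucleotides post-processed so no
spurious ORF reaches the scanner's minimum length.

Planted scenarios and the class each one's RE must receive:

====================================  =================================
ordinary_complete                     (not solitary; negative control)
separated_with_ordinary_ortholog      separated_system_member
separated_without_ortholog            no_orthologs
truncated_re                          probably_truncated
corrupted_mtase_nearby                corrupted_mtase_nearby
lone_re_no_mtase                      no_paired_mtase (>=2 planted; a
                                      single lone RE has no ortholog and
                                      is labelled no_orthologs instead)
methyl_directed_decoy                 (Type IV REs for the methyl screen)
====================================  =================================
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import io as rmio
from .model import GeneRecord, Replicon, Role, RMType, Topology, ValidationError

__all__ = ["ScenarioCounts", "CohortSpec", "SyntheticCohort", "generate_family", "generate_cohort"]

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# fixed, stop-free codon per residue (reverse translation)
CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCG", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}


@dataclass(frozen=True)
class ScenarioCounts:
    ordinary_complete: int = 1
    separated_with_ordinary_ortholog: int = 0
    separated_without_ortholog: int = 0
    truncated_re: int = 0
    corrupted_mtase_nearby: int = 0
    lone_re_no_mtase: int = 0
    methyl_directed_decoy: int = 0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value < 0:
                raise ValidationError(f"scenario count {name} must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    n_genomes: int
    scenarios: ScenarioCounts = ScenarioCounts()
    divergence: float = 0.10
    indel_rate: float = 0.0
    seed: int = 0
    topology: Topology = Topology.LINEAR
    replicon_length: Optional[int] = None  # cap; scenarios that cannot fit raise
    separation_bp: int = 12000
    mge_fraction: float = 0.0  # fraction of separated systems given a nearby transposase
    re_len: int = 220
    mtase_len: int = 180
    s_len: int = 160
    decoy_len: int = 240
    min_orf_nt: int = 150

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ValidationError("n_genomes must be >= 1")
        if not (0.0 <= self.divergence <= 0.6):
            raise ValidationError("divergence must lie in [0, 0.6]")
        if not (0.0 <= self.mge_fraction <= 1.0):
            raise ValidationError("mge_fraction must lie in [0, 1]")
        if self.separation_bp <= 4000:
            raise ValidationError("separation_bp must exceed the 4 kb rule to plant separated systems")


# ---------------------------------------------------------------------------
# protein families
# ---------------------------------------------------------------------------

def _random_protein(rng: np.random.Generator, length: int) -> str:
    body = "".join(AA20[i] for i in rng.integers(0, 20, size=length - 1))
    return "M" + body


def _mutate(rng: np.random.Generator, root: str, divergence: float, indel_rate: float) -> str:
    chars = list(root)
    for i in range(1, len(chars)):  # position 0 keeps the start methionine
        if rng.random() < divergence:
            alternatives = AA20.replace(chars[i], "")
            chars[i] = alternatives[rng.integers(0, len(alternatives))]
    if indel_rate > 0:
        out = []
        for i, c in enumerate(chars):
            if i > 0 and rng.random() < indel_rate:
                if rng.random() < 0.5:
                    continue  # deletion
                out.append(c)
                out.append(AA20[rng.integers(0, 20)])  # insertion
            else:
                out.append(c)
        chars = out
    return "".join(chars)


def generate_family(
    root_length: int,
    n_members: int,
    divergence: float,
    seed: int,
    indel_rate: float = 0.0,
) -> List[str]:
    """Protein family: each member derived from one random root by i.i.d. substitutions.

    Substitution-only expected pairwise identity is (1-d)^2 + d^2/19 per
    site.  Byte-identical output for identical arguments.
    """
    if root_length < 50:
        raise ValidationError("root_length must be >= 50")
    if n_members < 1:
        raise ValidationError("n_members must be >= 1")
    rng = np.random.default_rng(seed)
    root = _random_protein(rng, root_length)
    return [_mutate(rng, root, divergence, indel_rate) for _ in range(n_members)]


def _family(rng: np.random.Generator, length: int, n: int, d: float, indel: float) -> Tuple[str, List[str]]:
    root = _random_protein(rng, length)
    return root, [_mutate(rng, root, d, indel) for _ in range(n)]


# ---------------------------------------------------------------------------
# nucleotide layer
# ---------------------------------------------------------------------------

def _reverse_complement(seq: str) -> str:
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    return "".join(comp[c] for c in reversed(seq))


# 12 nt carrying a stop codon in all six frames; equal to its own reverse
# complement, so strand does not matter
_STOP_ISLAND = "TTAATTAATTAA"


def _sterile_intergenic(rng: np.random.Generator, length: int, min_orf_nt: int) -> str:
    """Random nucleotides interleaved with stop islands so no ORF reaches min_orf_nt."""
    if length <= 0:
        return ""
    # chunk + island + chunk bounds any stop-free run by 2*chunk + 24 < min_orf_nt
    chunk = max(3, (min_orf_nt - 30) // 2)
    parts: List[str] = []
    remaining = length
    while remaining > 0:
        take = min(chunk, remaining)
        parts.append("".join("ACGT"[i] for i in rng.integers(0, 4, size=take)))
        remaining -= take
        if remaining > 0:
            island = _STOP_ISLAND[: min(len(_STOP_ISLAND), remaining)]
            parts.append(island)
            remaining -= len(island)
    return "".join(parts)


def _coding_nt(protein: str) -> str:
    return "".join(CODON[c] for c in protein)


@dataclass
class _PlannedGene:
    gene_id: str
    role: Role
    rm_type: RMType
    protein: Optional[str]
    system_id: Optional[str]
    corrupted: bool = False
    corrupt_mode: Optional[str] = None  # frameshift | stop
    product: Optional[str] = None
    strand: str = "+"


class _GenomeBuilder:
    def __init__(self, genome_id: str, rng: np.random.Generator, min_orf_nt: int):
        self.genome_id = genome_id
        self.rng = rng
        self.min_orf_nt = min_orf_nt
        self.chunks: List[str] = []
        self.pos = 0
        self.genes: List[GeneRecord] = []
        self.proteins: Dict[str, str] = {}

    def spacer(self, length: int) -> None:
        chunk = _sterile_intergenic(self.rng, length, self.min_orf_nt)
        self.chunks.append(chunk)
        self.pos += len(chunk)

    def gene(self, plan: _PlannedGene) -> GeneRecord:
        coding = _coding_nt(plan.protein)
        if plan.corrupt_mode == "frameshift":
            cut = (len(coding) // 2) // 3 * 3 + 1
            coding = coding[:cut] + coding[cut + 1 :]
        elif plan.corrupt_mode == "stop":
            mid = (len(coding) // 2) // 3 * 3
            coding = coding[:mid] + "TAG" + coding[mid + 3 :]
        segment = coding + "TAA"
        if plan.strand == "-":
            segment = _reverse_complement(segment)
        # flanking in-frame stops terminate the gene's reading frame cleanly
        self.chunks.append("TAA" + segment + "TTA")
        start = self.pos + 3
        end = start + len(segment)
        self.pos += len(segment) + 6
        record = GeneRecord(
            gene_id=plan.gene_id,
            genome_id=self.genome_id,
            replicon_id=f"{self.genome_id}_rep",
            start=start,
            end=end,
            strand=plan.strand,
            role=plan.role,
            rm_type=plan.rm_type,
            corrupted=plan.corrupted,
            protein_seq=None if plan.corrupted else plan.protein,
            system_id=plan.system_id,
            product=plan.product,
        )
        self.genes.append(record)
        if not plan.corrupted and plan.protein:
            self.proteins[plan.gene_id] = plan.protein
        return record

    def finish(self, topology: Topology, max_length: Optional[int]) -> Replicon:
        self.spacer(int(self.rng.integers(400, 800)))
        sequence = "".join(self.chunks)
        if max_length is not None:
            if len(sequence) > max_length:
                raise ValidationError(
                    f"genome {self.genome_id}: planted scenarios need {len(sequence)} bp, "
                    f"replicon_length caps at {max_length}"
                )
            if len(sequence) < max_length:
                sequence += _sterile_intergenic(
                    self.rng, max_length - len(sequence), self.min_orf_nt
                )
        return Replicon(
            id=f"{self.genome_id}_rep",
            genome_id=self.genome_id,
            length=len(sequence),
            topology=topology,
            sequence=sequence,
        )


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    spec: CohortSpec
    genes: List[GeneRecord]
    replicons: List[Replicon]
    proteins: Dict[str, str]
    mtase_refs: Dict[str, str]
    truth: Dict

    def write(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        rmio.write_annotation(self.genes, self.replicons, os.path.join(outdir, "annotation.tsv"))
        rmio.write_annotation(
            self.genes, self.replicons, os.path.join(outdir, "annotation.gff3"), dialect="gff3"
        )
        rmio.write_fasta(
            {r.id: r.sequence for r in self.replicons}, os.path.join(outdir, "replicons.fasta")
        )
        rmio.write_fasta(self.proteins, os.path.join(outdir, "proteins.fasta"))
        rmio.write_fasta(self.mtase_refs, os.path.join(outdir, "mtase_refs.fasta"))
        with open(os.path.join(outdir, "truth.json"), "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _strand(rng: np.random.Generator) -> str:
    return "+" if rng.random() < 0.5 else "-"


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Build a cohort of annotated genomes with planted scenarios and truth labels."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genomes
    sc = spec.scenarios
    d = spec.divergence
    indel = spec.indel_rate

    builders = [
        _GenomeBuilder(f"G{idx:03d}", rng, spec.min_orf_nt) for idx in range(n)
    ]
    for b in builders:
        b.spacer(int(rng.integers(400, 800)))

    # inter-block spacing keeps scenarios out of each other's windows;
    # with planted MGEs it must exceed the 20 kb neighborhood as well
    block_gap = 21000 if spec.mge_fraction > 0 else 6500

    mtase_refs: Dict[str, str] = {}
    truth: Dict = {
        "seed": spec.seed,
        "n_genomes": n,
        "divergence": d,
        "solitary_classes": {},
        "separated_partners": {},
        "non_solitary_res": [],
        "mge_near_system": {},
        "methyl_directed": [],
        "families": {},
    }

    host_cursor = 0

    def next_host() -> int:
        nonlocal host_cursor
        h = host_cursor % n
        host_cursor += 1
        return h

    def support_of(h: int) -> int:
        if n < 2:
            raise ValidationError("scenarios with supporting genomes need >= 2 genomes")
        return (h + 1 + n // 2) % n if (h + 1 + n // 2) % n != h else (h + 1) % n

    def pad(builder: _GenomeBuilder) -> None:
        builder.spacer(int(rng.integers(block_gap, block_gap + 1500)))

    scen_idx = 0

    def fam_id(kind: str, role: str) -> str:
        return f"fam_{kind}{scen_idx:02d}_{role}"

    def add_complete_system(
        b: _GenomeBuilder, tag: str, rm_type: RMType, re_prot: str, mt_prot: str,
        s_prot: Optional[str] = None,
    ) -> Tuple[GeneRecord, GeneRecord]:
        sysid = f"{b.genome_id}_{tag}_sys"
        re_rec = b.gene(_PlannedGene(f"{b.genome_id}_{tag}_RE", Role.RE, rm_type, re_prot, sysid, strand=_strand(rng)))
        b.spacer(int(rng.integers(120, 260)))
        mt_rec = b.gene(_PlannedGene(f"{b.genome_id}_{tag}_MT", Role.MTASE, rm_type, mt_prot, sysid, strand=_strand(rng)))
        if s_prot is not None:
            b.spacer(int(rng.integers(120, 260)))
            b.gene(_PlannedGene(f"{b.genome_id}_{tag}_S", Role.S_SUBUNIT, rm_type, s_prot, sysid, strand=_strand(rng)))
        return re_rec, mt_rec

    type_cycle = (RMType.II, RMType.I, RMType.III)

    # --- ordinary complete systems (never solitary) --------------------------------
    for k in range(sc.ordinary_complete):
        scen_idx += 1
        h = next_host()
        rm_type = type_cycle[k % 3]
        _, re_members = _family(rng, spec.re_len, 1, d, indel)
        mt_root, mt_members = _family(rng, spec.mtase_len, 1, d, indel)
        mtase_refs[fam_id("ord", "MT")] = mt_root
        truth["families"].setdefault(fam_id("ord", "RE"), [])
        s_prot = _random_protein(rng, spec.s_len) if rm_type is RMType.I else None
        b = builders[h]
        re_rec, _ = add_complete_system(b, f"ord{scen_idx:02d}", rm_type, re_members[0], mt_members[0], s_prot)
        truth["non_solitary_res"].append(re_rec.gene_id)
        truth["families"][fam_id("ord", "RE")].append(re_rec.gene_id)
        pad(b)

    # --- separated systems with an ordinary orthologous system ---------------------
    n_mge = round(sc.separated_with_ordinary_ortholog * spec.mge_fraction)
    for k in range(sc.separated_with_ordinary_ortholog):
        scen_idx += 1
        h = next_host()
        s_ = support_of(h)
        rm_type = RMType.I if k % 2 else RMType.II
        _, re_members = _family(rng, spec.re_len, 2, d, indel)
        mt_root, mt_members = _family(rng, spec.mtase_len, 2, d, indel)
        mtase_refs[fam_id("sep", "MT")] = mt_root
        s_root, s_members = (
            _family(rng, spec.s_len, 2, d, indel) if rm_type is RMType.I else (None, [None, None])
        )
        tag = f"sep{scen_idx:02d}"
        b = builders[h]
        re_rec = b.gene(_PlannedGene(f"{b.genome_id}_{tag}_RE", Role.RE, rm_type, re_members[0],
                                     f"{b.genome_id}_{tag}_resys", strand=_strand(rng)))
        if k < n_mge:
            b.spacer(int(rng.integers(2000, 3000)))
            # low-complexity filler protein: must not resemble any MTase reference,
            # or the vicinity ORF scan would see a spurious novel MTase
            mge_prot = "M" + "NPGS" * 37 + "NPG"
            b.gene(_PlannedGene(f"{b.genome_id}_{tag}_MGE", Role.OTHER, RMType.UNKNOWN,
                                mge_prot, None,
                                product="IS481 family transposase", strand=_strand(rng)))
            truth["mge_near_system"][re_rec.gene_id] = True
        else:
            truth["mge_near_system"][re_rec.gene_id] = False
        b.spacer(spec.separation_bp + int(rng.integers(0, 1500)))
        mt_rec = b.gene(_PlannedGene(f"{b.genome_id}_{tag}_MT", Role.MTASE, rm_type, mt_members[0],
                                     f"{b.genome_id}_{tag}_mtsys", strand=_strand(rng)))
        if rm_type is RMType.I:
            b.spacer(int(rng.integers(120, 260)))
            b.gene(_PlannedGene(f"{b.genome_id}_{tag}_S", Role.S_SUBUNIT, rm_type, s_members[0],
                                f"{b.genome_id}_{tag}_mtsys", strand=_strand(rng)))
        pad(b)
        bs = builders[s_]
        sup_re, _ = add_complete_system(bs, tag, rm_type, re_members[1], mt_members[1],
                                        s_members[1] if rm_type is RMType.I else None)
        truth["non_solitary_res"].append(sup_re.gene_id)
        pad(bs)
        truth["solitary_classes"][re_rec.gene_id] = "separated_system_member"
        truth["separated_partners"][re_rec.gene_id] = [mt_rec.gene_id]

    # --- separated geometry with no ortholog anywhere -> no_orthologs --------------
    for k in range(sc.separated_without_ortholog):
        scen_idx += 1
        h = next_host()
        rm_type = RMType.II
        _, re_members = _family(rng, spec.re_len, 1, d, indel)
        mt_root, mt_members = _family(rng, spec.mtase_len, 1, d, indel)
        mtase_refs[fam_id("sepno", "MT")] = mt_root
        tag = f"sepno{scen_idx:02d}"
        b = builders[h]
        re_rec = b.gene(_PlannedGene(f"{b.genome_id}_{tag}_RE", Role.RE, rm_type, re_members[0],
                                     f"{b.genome_id}_{tag}_resys", strand=_strand(rng)))
        b.spacer(spec.separation_bp + int(rng.integers(0, 1500)))
        b.gene(_PlannedGene(f"{b.genome_id}_{tag}_MT", Role.MTASE, rm_type, mt_members[0],
                            f"{b.genome_id}_{tag}_mtsys", strand=_strand(rng)))
        pad(b)
        truth["solitary_classes"][re_rec.gene_id] = "no_orthologs"

    # --- truncated REs -------------------------------------------------------------
    for k in range(sc.truncated_re):
        scen_idx += 1
        h = next_host()
        s_ = support_of(h)
        rm_type = RMType.III if k % 2 else RMType.II
        _, re_members = _family(rng, spec.re_len, 2, d, indel)
        mt_root, mt_members = _family(rng, spec.mtase_len, 1, d, indel)
        mtase_refs[fam_id("trunc", "MT")] = mt_root
        tag = f"trunc{scen_idx:02d}"
        fragment = re_members[0][: int(0.6 * len(re_members[0]))]
        b = builders[h]
        re_rec = b.gene(_PlannedGene(f"{b.genome_id}_{tag}_RE", Role.RE, rm_type, fragment,
                                     f"{b.genome_id}_{tag}_resys", strand=_strand(rng)))
        pad(b)
        bs = builders[s_]
        sup_re, _ = add_complete_system(bs, tag, rm_type, re_members[1], mt_members[0])
        truth["non_solitary_res"].append(sup_re.gene_id)
        pad(bs)
        truth["solitary_classes"][re_rec.gene_id] = "probably_truncated"

    # --- corrupted MTase in the vicinity -------------------------------------------
    for k in range(sc.corrupted_mtase_nearby):
        scen_idx += 1
        h = next_host()
        s_ = support_of(h)
        rm_type = RMType.II
        _, re_members = _family(rng, spec.re_len, 2, d, indel)
        mt_root, mt_members = _family(rng, spec.mtase_len, 2, d, indel)
        mtase_refs[fam_id("corr", "MT")] = mt_root
        tag = f"corr{scen_idx:02d}"
        b = builders[h]
        sysid = f"{b.genome_id}_{tag}_sys"
        re_rec = b.gene(_PlannedGene(f"{b.genome_id}_{tag}_RE", Role.RE, rm_type, re_members[0],
                                     sysid, strand=_strand(rng)))
        b.spacer(int(rng.integers(200, 400)))
        mode = "frameshift" if k % 2 == 0 else "stop"
        b.gene(_PlannedGene(f"{b.genome_id}_{tag}_MTps", Role.MTASE, rm_type, mt_members[0],
                            sysid, corrupted=True, corrupt_mode=mode, strand=_strand(rng)))
        pad(b)
        bs = builders[s_]
        sup_re, _ = add_complete_system(bs, tag, rm_type, re_members[1], mt_members[1])
        truth["non_solitary_res"].append(sup_re.gene_id)
        pad(bs)
        truth["solitary_classes"][re_rec.gene_id] = "corrupted_mtase_nearby"

    # --- lone REs sharing one family -> no_paired_mtase ----------------------------
    if sc.lone_re_no_mtase:
        scen_idx += 1
        count = sc.lone_re_no_mtase
        if count > n:
            raise ValidationError("lone_re_no_mtase count cannot exceed n_genomes")
        _, re_members = _family(rng, spec.re_len, count, d, indel)
        label = "no_paired_mtase" if count >= 2 else "no_orthologs"
        for k in range(count):
            h = next_host()
            b = builders[h]
            tag = f"lone{scen_idx:02d}_{k}"
            re_rec = b.gene(_PlannedGene(f"{b.genome_id}_{tag}_RE", Role.RE, RMType.II,
                                         re_members[k], f"{b.genome_id}_{tag}_resys",
                                         strand=_strand(rng)))
            pad(b)
            truth["solitary_classes"][re_rec.gene_id] = label

    # --- methyl-directed (Type IV) decoys ------------------------------------------
    if sc.methyl_directed_decoy:
        scen_idx += 1
        count = sc.methyl_directed_decoy
        _, decoys = _family(rng, spec.decoy_len, count, d, indel)
        for k in range(count):
            h = next_host()
            b = builders[h]
            tag = f"deco{scen_idx:02d}_{k}"
            rec = b.gene(_PlannedGene(f"{b.genome_id}_{tag}_RE", Role.RE, RMType.IV,
                                      decoys[k], f"{b.genome_id}_{tag}_sys",
                                      strand=_strand(rng)))
            pad(b)
            truth["methyl_directed"].append(rec.gene_id)

    replicons = [b.finish(spec.topology, spec.replicon_length) for b in builders]
    genes: List[GeneRecord] = []
    proteins: Dict[str, str] = {}
    for b in builders:
        genes.extend(b.genes)
        proteins.update(b.proteins)
    genes.sort(key=lambda g: g.gene_id)

    return SyntheticCohort(
        spec=spec,
        genes=genes,
        replicons=sorted(replicons, key=lambda r: r.id),
        proteins=dict(sorted(proteins.items())),
        mtase_refs=dict(sorted(mtase_refs.items())),
        truth=truth,
    )
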