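"""End-to-end orchestration: detection -> truncation -> orthology -> partner
search -> classification -> methyl screen -> neighborhood scan -> reports.

Stage order follows the analysis it implements: corrupted and probably
truncated REs are set aside first, then orthologs are searched, then the
remaining solitary REs are classified.  Runs are deterministic for a fixed
seed and configuration; output files carry no timestamps so re-runs are
byte-identical.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence

import yaml

from . import align, io as rmio, methyl, neighborhood, orthology, separated as sep, solitary, truncation
from .model import (
    GeneRecord,
    Replicon,
    RMSystem,
    Role,
    RMType,
    Thresholds,
    ValidationError,
    build_systems,
)

__all__ = ["RunConfig", "AnalysisResult", "analyze_cohort", "run_pipeline"]

logger = logging.getLogger("rmscan")

# methyl-directed types are screened, not classified, as solitary candidates
_METHYL_TYPES = (RMType.IIM, RMType.IV)


@dataclass
class RunConfig:
    input_dir: str
    output_dir: str
    annotation: str = "annotation.tsv"
    dialect: str = "rebase_tsv"
    proteins: str = "proteins.fasta"
    replicon_fasta: Optional[str] = "replicons.fasta"
    mtase_refs: Optional[str] = "mtase_refs.fasta"
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0
    log_level: str = "INFO"
    backend: str = "internal"  # internal aligner; 'tabular:<path>' reads external hits

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        thr = Thresholds(**data.pop("thresholds", {}))
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(thresholds=thr, **data)


@dataclass
class AnalysisResult:
    systems: Dict[str, RMSystem]
    scans: Dict[str, solitary.VicinityScanResult]
    solitary_res: List[GeneRecord]
    truncation: Dict[str, bool]
    truncation_evidence: List[truncation.TruncationEvidence]
    re_pairs: List[orthology.OrthologPair]
    re_groups: List[orthology.OrthologGroup]
    partners: Dict[str, List[sep.PutativeRMSystem]]
    classifications: List[sep.SolitaryClassification]
    separated_systems: List[sep.PutativeRMSystem]
    group_summary: List[sep.GroupSummary]
    screen: methyl.ScreenResult
    mge_scans: Dict[str, List[neighborhood.MGEHit]]
    mge_enrichment: Optional[float]


def analyze_cohort(
    genes: Sequence[GeneRecord],
    replicons: Sequence[Replicon],
    mtase_refs: Mapping[str, str],
    thresholds: Thresholds = Thresholds(),
    seed: int = 0,
) -> AnalysisResult:
    genes = sorted(genes, key=lambda g: g.gene_id)
    rep_by_id = {r.id: r for r in replicons}
    genes_by_replicon: Dict[str, List[GeneRecord]] = {}
    for g in genes:
        genes_by_replicon.setdefault(g.replicon_id, []).append(g)

    logger.info("stage completeness: grouping %d genes into systems", len(genes))
    systems = build_systems(genes)

    logger.info("stage solitary: vicinity scans")
    candidates = [
        g
        for g in solitary.solitary_candidates(systems)
        if g.rm_type not in _METHYL_TYPES
    ]
    scans: Dict[str, solitary.VicinityScanResult] = {}
    solitary_res: List[GeneRecord] = []
    for re_gene in candidates:
        replicon = rep_by_id.get(re_gene.replicon_id)
        if replicon is None:
            raise ValidationError(f"gene {re_gene.gene_id} references unknown replicon")
        if replicon.sequence is None:
            logger.warning(
                "no sequence for replicon %s; vicinity scan of %s is annotation-only",
                replicon.id,
                re_gene.gene_id,
            )
        scan = solitary.scan_vicinity_for_mtases(
            re_gene,
            replicon,
            genes_by_replicon.get(re_gene.replicon_id, ()),
            mtase_refs,
            thresholds,
        )
        scans[re_gene.gene_id] = scan
        if solitary.call_solitary(re_gene, scan):
            solitary_res.append(re_gene)

    cache = align.SimilarityCache({g.gene_id: g.protein_seq for g in genes if g.protein_seq})

    logger.info("stage truncation: %d solitary REs", len(solitary_res))
    complete_res = [
        g
        for s in systems.values()
        if s.completeness == "complete"
        for g in s.re_genes
        if not g.corrupted and g.protein_seq
    ]
    trunc_flags: Dict[str, bool] = {}
    trunc_rows: List[truncation.TruncationEvidence] = []
    for re_gene in solitary_res:
        flag, rows = truncation.is_probably_truncated(re_gene, complete_res, thresholds, cache)
        trunc_flags[re_gene.gene_id] = flag
        trunc_rows.extend(rows)
    full_length = [g for g in solitary_res if not trunc_flags[g.gene_id]]

    logger.info("stage orthology: BBH over RE genes")
    ortho_universe = [
        g
        for g in genes
        if g.role is Role.RE and not g.corrupted and g.protein_seq
        and g.rm_type not in _METHYL_TYPES
        and not trunc_flags.get(g.gene_id, False)
    ]
    re_pairs = orthology.all_bbh_pairs(ortho_universe, Role.RE, thresholds, cache=cache)
    re_groups = orthology.build_groups(re_pairs)
    with_orthologs = {p.gene_a.gene_id for p in re_pairs} | {p.gene_b.gene_id for p in re_pairs}

    logger.info("stage separated: partner MTase search for %d REs", len(full_length))
    partners: Dict[str, List[sep.PutativeRMSystem]] = {}
    for re_gene in full_length:
        if re_gene.gene_id not in with_orthologs:
            partners[re_gene.gene_id] = []
            continue
        partners[re_gene.gene_id] = sep.find_partner_mtase(
            re_gene, genes, systems, re_pairs, rep_by_id, thresholds, cache=cache
        )

    logger.info("stage classify: %d solitary REs", len(solitary_res))
    classifications = [
        sep.classify_solitary(
            re_gene,
            trunc_flags[re_gene.gene_id],
            re_gene.gene_id in with_orthologs,
            partners.get(re_gene.gene_id, []),
            scans.get(re_gene.gene_id),
        )
        for re_gene in solitary_res
    ]

    separated_systems = [
        p
        for re_gene in full_length
        for p in partners.get(re_gene.gene_id, [])
        if p.status == "separated"
    ]
    group_summary = sep.summarize_groups(separated_systems, re_groups, systems)

    logger.info("stage screen: solitary REs vs methyl-directed REs")
    screen_solitary = {g.gene_id: g.protein_seq for g in full_length}
    screen_methyl = {
        g.gene_id: g.protein_seq
        for g in genes
        if g.role is Role.RE and g.rm_type in _METHYL_TYPES and g.protein_seq and not g.corrupted
    }
    screen = methyl.screen_against_methyl_directed(
        screen_solitary, screen_methyl, thresholds, seed=seed
    )

    logger.info("stage neighborhood: MGE scan around %d separated systems", len(separated_systems))
    mge_scans: Dict[str, List[neighborhood.MGEHit]] = {}
    for system in separated_systems:
        for anchor in (system.re_gene, system.mtase_gene):
            if anchor.gene_id not in mge_scans:
                mge_scans[anchor.gene_id] = neighborhood.scan_mge(
                    anchor,
                    genes_by_replicon.get(anchor.replicon_id, ()),
                    rep_by_id,
                    thresholds=thresholds,
                )
    enrichment = neighborhood.mge_enrichment_summary(separated_systems, mge_scans)

    return AnalysisResult(
        systems=systems,
        scans=scans,
        solitary_res=solitary_res,
        truncation=trunc_flags,
        truncation_evidence=trunc_rows,
        re_pairs=re_pairs,
        re_groups=re_groups,
        partners=partners,
        classifications=classifications,
        separated_systems=separated_systems,
        group_summary=group_summary,
        screen=screen,
        mge_scans=mge_scans,
        mge_enrichment=enrichment,
    )


# ---------------------------------------------------------------------------
# file-level run
# ---------------------------------------------------------------------------

def _fmt_sep(separation: float) -> str:
    return "inf" if math.isinf(separation) else str(int(separation))


def write_bundle(result: AnalysisResult, outdir: str) -> Dict[str, str]:
    os.makedirs(outdir, exist_ok=True)
    files: Dict[str, str] = {}

    def path(name: str) -> str:
        files[name] = name
        return os.path.join(outdir, name)

    rmio.write_report(result.classifications, path("table1.json"), fmt="json")
    rmio.write_report(result.classifications, path("table1.tsv"), fmt="tsv")

    with open(path("classifications.tsv"), "w") as fh:
        fh.write("re_gene_id\tgenome_id\trm_type\tverdict\tseparated_partners\n")
        for c in sorted(result.classifications, key=lambda c: c.re_gene.gene_id):
            partners = ",".join(c.evidence.get("partners", []))
            fh.write(
                f"{c.re_gene.gene_id}\t{c.re_gene.genome_id}\t{c.re_gene.rm_type.value}"
                f"\t{c.verdict}\t{partners}\n"
            )

    with open(path("putative_systems.tsv"), "w") as fh:
        fh.write("re_gene_id\tmtase_gene_id\tgenome_id\tseparation_bp\tstatus\tprovenance\ts_genes\n")
        rows = sorted(
            (p for ps in result.partners.values() for p in ps),
            key=lambda p: (p.re_gene.gene_id, p.mtase_gene.gene_id),
        )
        for p in rows:
            prov = ",".join(
                f"{v.genome_id}:{v.re_gene_id}:{v.mtase_gene_id}" for v in p.provenance
            )
            s_ids = ",".join(g.gene_id for g in p.s_genes)
            fh.write(
                f"{p.re_gene.gene_id}\t{p.mtase_gene.gene_id}\t{p.genome_id}"
                f"\t{_fmt_sep(p.separation_bp)}\t{p.status}\t{prov}\t{s_ids}\n"
            )

    with open(path("ortholog_pairs.tsv"), "w") as fh:
        fh.write("gene_a\tgene_b\trole\tidentity_ab\tcoverage_longer_ab\n")
        for p in result.re_pairs:
            fh.write(
                f"{p.key[0]}\t{p.key[1]}\t{p.role.value}"
                f"\t{p.hit_ab.identity:.4f}\t{p.hit_ab.coverage_longer:.4f}\n"
            )

    with open(path("ortholog_groups.tsv"), "w") as fh:
        fh.write("group_id\trole\trm_type\tn_members\tmembers\n")
        for g in result.re_groups:
            fh.write(
                f"{g.group_id}\t{g.role.value}\t{g.rm_type.value}"
                f"\t{len(g.members)}\t{','.join(g.member_ids)}\n"
            )

    with open(path("table2.tsv"), "w") as fh:
        fh.write("group_id\trm_type\tn_systems\tn_annotated\tn_separated\tn_solitary\n")
        for row in result.group_summary:
            fh.write(
                f"{row.group_id}\t{row.rm_type}\t{row.n_systems}\t{row.n_annotated}"
                f"\t{row.n_separated}\t{row.n_solitary}\n"
            )

    truncation.write_evidence_tsv(result.truncation_evidence, path("truncation_evidence.tsv"))

    with open(path("screen_clusters.tsv"), "w") as fh:
        fh.write("cluster_id\tmixed\tmembers\n")
        for c in result.screen.clusters:
            fh.write(f"{c.cluster_id}\t{'true' if c.mixed else 'false'}\t{','.join(c.members)}\n")
    for cid, newick in sorted(result.screen.newicks.items()):
        with open(path(f"screen_{cid}.nwk"), "w") as fh:
            fh.write(newick + "\n")
    for cid, msa in sorted(result.screen.alignments.items()):
        rmio.write_fasta(dict(msa), path(f"screen_{cid}.afa"))

    with open(path("mge_hits.tsv"), "w") as fh:
        fh.write("anchor_gene_id\tmge_gene_id\tcategory\tdistance_bp\tproduct\n")
        for anchor in sorted(result.mge_scans):
            for h in result.mge_scans[anchor]:
                fh.write(
                    f"{h.anchor_gene_id}\t{h.mge_gene_id}\t{h.category}"
                    f"\t{h.distance_bp}\t{h.product}\n"
                )

    summary = {
        "schema_version": rmio.REPORT_SCHEMA_VERSION,
        "n_systems": len(result.systems),
        "n_complete_systems": sum(
            1 for s in result.systems.values() if s.completeness == "complete"
        ),
        "n_solitary": len(result.solitary_res),
        "n_probably_truncated": sum(1 for v in result.truncation.values() if v),
        "n_ortholog_groups": len(result.re_groups),
        "n_separated_systems": len(result.separated_systems),
        "mge_enrichment": result.mge_enrichment,
        "mixed_screen_clusters": [c.cluster_id for c in result.screen.clusters if c.mixed],
    }
    with open(path("summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    manifest = {"schema_version": rmio.REPORT_SCHEMA_VERSION, "files": sorted(files)}
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return files


def load_inputs(config: RunConfig):
    indir = config.input_dir
    genes, replicons = rmio.read_annotation(
        os.path.join(indir, config.annotation), dialect=config.dialect
    )
    prot_path = os.path.join(indir, config.proteins)
    if os.path.exists(prot_path):
        genes = rmio.attach_proteins(genes, rmio.read_fasta(prot_path))
    for g in genes:
        if not g.corrupted and g.role in (Role.RE, Role.MTASE, Role.S_SUBUNIT):
            g.require_protein()
    rep_path = (
        os.path.join(indir, config.replicon_fasta) if config.replicon_fasta else None
    )
    if rep_path and os.path.exists(rep_path):
        seqs = rmio.read_fasta(rep_path)
        replicons = [
            replace(r, sequence=seqs.get(r.id), length=len(seqs[r.id]) if r.id in seqs else r.length)
            for r in replicons
        ]
    else:
        logger.warning("replicon FASTA missing; detection will run annotation-only")
    refs_path = os.path.join(indir, config.mtase_refs) if config.mtase_refs else None
    mtase_refs = rmio.read_fasta(refs_path) if refs_path and os.path.exists(refs_path) else {}
    return genes, replicons, mtase_refs


def run_pipeline(config: RunConfig) -> AnalysisResult:
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    genes, replicons, mtase_refs = load_inputs(config)
    result = analyze_cohort(
        genes, replicons, mtase_refs, thresholds=config.thresholds, seed=config.seed
    )
    write_bundle(result, config.output_dir)
    logger.info("pipeline complete: %d outputs in %s", len(os.listdir(config.output_dir)), config.output_dir)
    return result
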