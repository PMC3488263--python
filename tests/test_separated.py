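import math

import pytest

from rmscan.model import (
    Replicon,
    RMType,
    Role,
    Thresholds,
    Topology,
    ValidationError,
    build_systems,
)
from rmscan.orthology import all_bbh_pairs, build_groups
from rmscan.separated import (
    classify_solitary,
    find_partner_mtase,
    gene_distance,
    summarize_groups,
)
from rmscan.solitary import VicinityScanResult
from rmscan.synth import generate_family

from conftest import make_gene

THR = Thresholds()


def _reps(*genomes, length=1_000_000, topology=Topology.LINEAR):
    return {
        f"{g}_chr": Replicon(id=f"{g}_chr", genome_id=g, length=length, topology=topology)
        for g in genomes
    }


class TestGeneDistance:
    def test_same_replicon_edge_to_edge(self):
        reps = _reps("G1")
        a = make_gene(gene_id="a", replicon_id="G1_chr", start=10_000, end=11_000)
        b = make_gene(gene_id="b", replicon_id="G1_chr", start=11_500, end=12_500)
        assert gene_distance(a, b, reps) == 500

    def test_overlap_is_zero(self):
        reps = _reps("G1")
        a = make_gene(gene_id="a", replicon_id="G1_chr", start=10_000, end=11_000)
        b = make_gene(gene_id="b", replicon_id="G1_chr", start=10_500, end=12_500)
        assert gene_distance(a, b, reps) == 0

    def test_160kb_is_separated(self):
        reps = _reps("G1")
        a = make_gene(gene_id="a", replicon_id="G1_chr", start=10_000, end=11_000)
        b = make_gene(gene_id="b", replicon_id="G1_chr", start=171_000, end=172_000)
        assert gene_distance(a, b, reps) == 160_000 > THR.separated_bp

    def test_circular_adjacent_across_origin(self):
        reps = _reps("G1", length=1_000_000, topology=Topology.CIRCULAR)
        a = make_gene(gene_id="a", replicon_id="G1_chr", start=0, end=1000)
        b = make_gene(gene_id="b", replicon_id="G1_chr", start=999_500, end=1_000_000)
        assert gene_distance(a, b, reps) == 0

    def test_different_replicons_infinite(self):
        reps = _reps("G1")
        reps["G1_pl"] = Replicon(id="G1_pl", genome_id="G1", length=50_000)
        a = make_gene(gene_id="a", replicon_id="G1_chr")
        b = make_gene(gene_id="b", replicon_id="G1_pl", start=100, end=700)
        assert math.isinf(gene_distance(a, b, reps))

    def test_different_genomes_rejected(self):
        reps = _reps("G1", "G2")
        a = make_gene(gene_id="a", genome_id="G1", replicon_id="G1_chr")
        b = make_gene(gene_id="b", genome_id="G2", replicon_id="G2_chr")
        with pytest.raises(ValidationError):
            gene_distance(a, b, reps)


def _planted_cohort(n_support=1, with_home_mtase=True, mtases_per_system=1, seed=5):
    """G1 holds the solitary RE (+ distant MTase(s)); support genomes hold
    complete orthologous systems."""
    re_fam = generate_family(160, 2 + n_support, divergence=0.08, seed=seed)
    mt_fams = [
        generate_family(140, 2 + n_support, divergence=0.08, seed=seed + 10 + i)
        for i in range(mtases_per_system)
    ]
    genes = []
    genomes = ["G1"] + [f"S{i}" for i in range(n_support)]
    reps = _reps(*genomes)

    sol = make_gene(
        gene_id="G1_re", genome_id="G1", replicon_id="G1_chr",
        start=10_000, end=10_480, role=Role.RE, protein_seq=re_fam[0],
        system_id="G1_resys",
    )
    genes.append(sol)
    if with_home_mtase:
        for i in range(mtases_per_system):
            genes.append(
                make_gene(
                    gene_id=f"G1_mt{i}", genome_id="G1", replicon_id="G1_chr",
                    start=30_000 + 5000 * i, end=30_420 + 5000 * i, role=Role.MTASE,
                    protein_seq=mt_fams[i][0], system_id=f"G1_mtsys{i}",
                )
            )
    for s in range(n_support):
        sid = f"S{s}_sys"
        genes.append(
            make_gene(
                gene_id=f"S{s}_re", genome_id=f"S{s}", replicon_id=f"S{s}_chr",
                start=10_000, end=10_480, role=Role.RE, protein_seq=re_fam[1 + s],
                system_id=sid,
            )
        )
        for i in range(mtases_per_system):
            genes.append(
                make_gene(
                    gene_id=f"S{s}_mt{i}", genome_id=f"S{s}", replicon_id=f"S{s}_chr",
                    start=11_000 + 600 * i, end=11_420 + 600 * i, role=Role.MTASE,
                    protein_seq=mt_fams[i][1 + s], system_id=sid,
                )
            )
    systems = build_systems(genes)
    pairs = all_bbh_pairs(genes, Role.RE)
    return sol, genes, systems, pairs, reps


class TestFindPartner:
    def test_recovers_partner_with_provenance(self):
        sol, genes, systems, pairs, reps = _planted_cohort()
        partners = find_partner_mtase(sol, genes, systems, pairs, reps)
        assert len(partners) == 1
        p = partners[0]
        assert p.mtase_gene.gene_id == "G1_mt0"
        assert p.status == "separated"
        assert p.separation_bp > THR.separated_bp
        assert [v.genome_id for v in p.provenance] == ["S0"]

    def test_chain_broken_without_home_mtase(self):
        sol, genes, systems, pairs, reps = _planted_cohort(with_home_mtase=False)
        assert find_partner_mtase(sol, genes, systems, pairs, reps) == []

    def test_two_supports_merge_provenance(self):
        sol, genes, systems, pairs, reps = _planted_cohort(n_support=2)
        partners = find_partner_mtase(sol, genes, systems, pairs, reps)
        assert len(partners) == 1
        assert len(partners[0].provenance) == 2
        assert sorted(v.genome_id for v in partners[0].provenance) == ["S0", "S1"]

    def test_two_mtase_cassettes_two_putative_systems(self):
        sol, genes, systems, pairs, reps = _planted_cohort(mtases_per_system=2)
        partners = find_partner_mtase(sol, genes, systems, pairs, reps)
        assert len(partners) == 2
        assert {p.mtase_gene.gene_id for p in partners} == {"G1_mt0", "G1_mt1"}
        assert all(p.status == "separated" for p in partners)


def _scan(re_id="re", corrupted_nearby=False):
    return VicinityScanResult(
        re_gene_id=re_id,
        intervals=((0, 10),),
        has_corrupted_mtase=corrupted_nearby,
    )


class TestClassifyPrecedence:
    def test_truncated_wins_over_partner(self):
        g = make_gene(gene_id="re")
        from rmscan.separated import PutativeRMSystem

        partner = PutativeRMSystem(
            re_gene=g, mtase_gene=make_gene(gene_id="mt", role=Role.MTASE),
            genome_id="G1", separation_bp=9000.0, status="separated",
        )
        c = classify_solitary(g, True, True, [partner], _scan())
        assert c.verdict == "probably_truncated"

    def test_no_orthologs(self):
        g = make_gene(gene_id="re")
        c = classify_solitary(g, False, False, [], _scan())
        assert c.verdict == "no_orthologs"

    def test_separated_member(self):
        sol, genes, systems, pairs, reps = _planted_cohort()
        partners = find_partner_mtase(sol, genes, systems, pairs, reps)
        c = classify_solitary(sol, False, True, partners, _scan(sol.gene_id))
        assert c.verdict == "separated_system_member"
        assert c.evidence["partners"] == ["G1_mt0"]

    def test_corrupted_nearby(self):
        g = make_gene(gene_id="re")
        c = classify_solitary(g, False, True, [], _scan(corrupted_nearby=True))
        assert c.verdict == "corrupted_mtase_nearby"

    def test_no_paired_default(self):
        g = make_gene(gene_id="re")
        c = classify_solitary(g, False, True, [], _scan())
        assert c.verdict == "no_paired_mtase"

    def test_ordinary_partner_is_not_separated(self):
        from rmscan.separated import PutativeRMSystem

        g = make_gene(gene_id="re")
        partner = PutativeRMSystem(
            re_gene=g, mtase_gene=make_gene(gene_id="mt", role=Role.MTASE),
            genome_id="G1", separation_bp=500.0, status="ordinary",
        )
        c = classify_solitary(g, False, True, [partner], _scan())
        assert c.verdict == "no_paired_mtase"


class TestSummarizeGroups:
    def test_three_system_group(self):
        sol, genes, systems, pairs, reps = _planted_cohort(n_support=2)
        partners = find_partner_mtase(sol, genes, systems, pairs, reps)
        groups = build_groups(pairs)
        rows = summarize_groups(partners, groups, systems)
        assert len(rows) == 1
        row = rows[0]
        assert (row.n_systems, row.n_annotated, row.n_separated, row.n_solitary) == (3, 2, 1, 1)

    def test_two_cassettes_exceed_solitary_count(self):
        sol, genes, systems, pairs, reps = _planted_cohort(mtases_per_system=2)
        partners = find_partner_mtase(sol, genes, systems, pairs, reps)
        groups = build_groups(pairs)
        rows = summarize_groups(partners, groups, systems)
        assert rows[0].n_separated == 2
        assert rows[0].n_solitary == 1

    def test_groups_without_separated_members_omitted(self):
        sol, genes, systems, pairs, reps = _planted_cohort()
        groups = build_groups(pairs)
        assert summarize_groups([], groups, systems) == []

    def test_removing_support_removes_separated_call(self):
        sol, genes, systems, pairs, reps = _planted_cohort()
        kept = [g for g in genes if not g.gene_id.startswith("S0")]
        systems2 = build_systems(kept)
        pairs2 = all_bbh_pairs(kept, Role.RE)
        assert find_partner_mtase(sol, kept, systems2, pairs2, reps) == []
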