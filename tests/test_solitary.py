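import numpy as np
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
from rmscan.solitary import (
    call_solitary,
    classify_completeness,
    scan_vicinity_for_mtases,
    six_frame_orfs,
    solitary_candidates,
    vicinity_interval,
)
from rmscan.synth import CODON, _sterile_intergenic

from conftest import make_gene


def _coding(protein):
    return "".join(CODON[c] for c in protein)


class TestCompleteness:
    def test_intact_pair_is_complete(self, gene_factory):
        re = gene_factory(gene_id="re", role=Role.RE, system_id="s")
        mt = gene_factory(gene_id="mt", role=Role.MTASE, system_id="s", start=12_000, end=13_000)
        assert classify_completeness(build_systems([re, mt])["s"]) == "complete"

    def test_corrupted_mtase_is_incomplete(self, gene_factory):
        re = gene_factory(gene_id="re", role=Role.RE, system_id="s")
        mt = gene_factory(
            gene_id="mt", role=Role.MTASE, system_id="s", start=12_000, end=13_000,
            corrupted=True, protein_seq=None,
        )
        assert classify_completeness(build_systems([re, mt])["s"]) == "incomplete"

    def test_lone_re_is_incomplete(self, gene_factory):
        re = gene_factory(gene_id="re", role=Role.RE, system_id="s")
        assert classify_completeness(build_systems([re])["s"]) == "incomplete"

    def test_empty_system_rejected(self):
        from rmscan.model import RMSystem

        with pytest.raises(ValidationError):
            classify_completeness(RMSystem(system_id="s", genome_id="g"))


class TestVicinityInterval:
    def test_plain_window(self, gene_factory, linear_replicon):
        g = gene_factory(start=10_000, end=11_000)
        assert vicinity_interval(g, 4000, linear_replicon) == ((6000, 15_000),)

    def test_clipped_at_origin(self, gene_factory, linear_replicon):
        g = gene_factory(start=1000, end=2000)
        assert vicinity_interval(g, 4000, linear_replicon) == ((0, 6000),)

    def test_circular_wraps(self, gene_factory, circular_replicon):
        g = gene_factory(replicon_id="pCIRC", start=500, end=1500)
        assert vicinity_interval(g, 4000, circular_replicon) == ((96_500, 100_000), (0, 5500))

    def test_window_must_be_positive(self, gene_factory, linear_replicon):
        with pytest.raises(ValidationError):
            vicinity_interval(gene_factory(), 0, linear_replicon)

    def test_gene_outside_replicon_rejected(self, gene_factory):
        small = Replicon(id="chr", genome_id="G1", length=10_500)
        g = gene_factory(start=10_000, end=11_000)
        with pytest.raises(ValidationError):
            vicinity_interval(g, 4000, small)


class TestSixFrameOrfs:
    def test_finds_planted_orf_on_both_strands(self):
        rng = np.random.default_rng(5)
        protein = "M" + "HEAVYWIGHTCHAMP" * 5  # 76 aa
        coding = _coding(protein) + "TAA"
        for strand in "+-":
            insert = coding
            if strand == "-":
                comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
                insert = "".join(comp[c] for c in reversed(coding))
            seq = (
                _sterile_intergenic(rng, 300, 150)
                + "TAA" + insert + "TTA"
                + _sterile_intergenic(rng, 300, 150)
            )
            orfs = six_frame_orfs(seq, 150)
            assert any(protein in p for _s, _e, st_, _f, p in orfs if st_ == strand)

    def test_sterile_sequence_has_no_orfs(self):
        rng = np.random.default_rng(11)
        seq = _sterile_intergenic(rng, 5000, 150)
        assert six_frame_orfs(seq, 150) == []

    def test_coordinates_consistent(self):
        seq = "TAA" + _coding("M" + "KLVAPQRST" * 8) + "TAATT"
        orfs = six_frame_orfs(seq, 150)
        plus = [o for o in orfs if o[2] == "+"]
        assert plus
        s, e, _, _, prot = plus[0]
        assert (e - s) % 3 == 0
        assert len(prot) == (e - s) // 3


def _build_scan_fixture(mtase_protein, corrupted=False, distance=1000, window_ok=True):
    """One RE + one MTase gene with real sequence on a linear replicon."""
    rng = np.random.default_rng(17)
    re_prot = "M" + "WQKLVANDEFGHIRSTY" * 13
    re_nt = "TAA" + _coding(re_prot) + "TAA" + "TTA"
    mt_nt = "TAA" + _coding(mtase_protein) + "TAA" + "TTA"
    if corrupted:
        cut = len(mt_nt) // 2 // 3 * 3 + 1
        mt_nt = mt_nt[:cut] + mt_nt[cut + 1 :]
    lead = _sterile_intergenic(rng, 5000, 150)
    gap = _sterile_intergenic(rng, distance, 150)
    tail = _sterile_intergenic(rng, 6000, 150)
    seq = lead + re_nt + gap + mt_nt + tail
    re_start = len(lead) + 3
    re_end = re_start + len(_coding(re_prot)) + 3
    mt_start = len(lead) + len(re_nt) + len(gap) + 3
    mt_end = mt_start + len(mt_nt) - 7 if corrupted else mt_start + len(_coding(mtase_protein)) + 3
    rep = Replicon(id="chr", genome_id="G1", length=len(seq), sequence=seq)
    re_gene = make_gene(
        gene_id="re", start=re_start, end=re_end, role=Role.RE, protein_seq=re_prot,
        system_id="sys_re",
    )
    mt_gene = make_gene(
        gene_id="mt", start=mt_start, end=mt_end, role=Role.MTASE,
        corrupted=corrupted, protein_seq=None if corrupted else mtase_protein,
        system_id="sys_mt",
    )
    return re_gene, mt_gene, rep


MT_REF = "M" + "GDNAQETYLRKWIVCHSPF" * 10  # 191 aa reference MTase


def _diverge(protein, d, seed):
    rng = np.random.default_rng(seed)
    aa = "ACDEFGHIKLMNPQRSTVWY"
    out = list(protein)
    for i in range(1, len(out)):
        if rng.random() < d:
            alt = aa.replace(out[i], "")
            out[i] = alt[rng.integers(0, len(alt))]
    return "".join(out)


class TestScanVicinity:
    def test_planted_mtase_found_via_annotation_and_orf(self):
        mt = _diverge(MT_REF, 0.05, seed=3)
        re_gene, mt_gene, rep = _build_scan_fixture(mt, distance=1000)
        scan = scan_vicinity_for_mtases(re_gene, rep, [re_gene, mt_gene], {"ref": MT_REF})
        assert scan.has_noncorrupted_mtase
        assert not call_solitary(re_gene, scan)

    def test_unannotated_mtase_orf_detected(self):
        # same geometry, but the MTase is not in the annotation at all
        mt = _diverge(MT_REF, 0.05, seed=3)
        re_gene, _mt_gene, rep = _build_scan_fixture(mt, distance=1000)
        scan = scan_vicinity_for_mtases(re_gene, rep, [re_gene], {"ref": MT_REF})
        assert not scan.has_noncorrupted_mtase
        assert scan.has_novel_mtase_orf
        assert scan.candidate_orfs
        assert all(o.best_hit.evalue < 0.01 for o in scan.candidate_orfs)
        assert not call_solitary(re_gene, scan)

    def test_empty_vicinity_has_no_candidates(self):
        mt = _diverge(MT_REF, 0.05, seed=3)
        re_gene, mt_gene, rep = _build_scan_fixture(mt, distance=9000)  # outside 4 kb
        scan = scan_vicinity_for_mtases(re_gene, rep, [re_gene, mt_gene], {"ref": MT_REF})
        assert not scan.has_noncorrupted_mtase
        assert not scan.has_novel_mtase_orf
        assert call_solitary(re_gene, scan)

    def test_corrupted_mtase_flags_but_does_not_block(self):
        mt = _diverge(MT_REF, 0.05, seed=3)
        re_gene, mt_gene, rep = _build_scan_fixture(mt, corrupted=True, distance=1000)
        scan = scan_vicinity_for_mtases(re_gene, rep, [re_gene, mt_gene], {"ref": MT_REF})
        assert scan.has_corrupted_mtase
        assert not scan.has_noncorrupted_mtase
        # fragments of the pseudo-MTase are attributed to it, not to a novel ORF
        assert not scan.has_novel_mtase_orf
        assert call_solitary(re_gene, scan)

    def test_annotation_only_without_sequence(self, gene_factory, linear_replicon):
        re_gene = gene_factory(gene_id="re", role=Role.RE)
        mt_gene = gene_factory(
            gene_id="mt", role=Role.MTASE, start=12_000, end=13_000,
            protein_seq=MT_REF,
        )
        scan = scan_vicinity_for_mtases(re_gene, linear_replicon, [re_gene, mt_gene], {})
        assert scan.annotation_only
        assert scan.has_noncorrupted_mtase

    def test_boundary_mtase_at_exactly_4000_is_outside(self, gene_factory, linear_replicon):
        re_gene = gene_factory(gene_id="re", start=10_000, end=11_000, role=Role.RE)
        mt_at = gene_factory(gene_id="mt", role=Role.MTASE, start=15_000, end=16_000, protein_seq=MT_REF)
        scan = scan_vicinity_for_mtases(re_gene, linear_replicon, [re_gene, mt_at], {})
        assert not scan.has_noncorrupted_mtase
        assert call_solitary(re_gene, scan)
        mt_in = gene_factory(gene_id="mt2", role=Role.MTASE, start=14_999, end=16_000, protein_seq=MT_REF)
        scan2 = scan_vicinity_for_mtases(re_gene, linear_replicon, [re_gene, mt_in], {})
        assert not call_solitary(re_gene, scan2)

    def test_corrupted_re_rejected(self, gene_factory, linear_replicon):
        re_gene = gene_factory(gene_id="re", corrupted=True, protein_seq=None)
        scan = scan_vicinity_for_mtases(re_gene, linear_replicon, [re_gene], {})
        with pytest.raises(ValidationError):
            call_solitary(re_gene, scan)

    @pytest.mark.parametrize("window", [4000, 6000, 9500, 12_000])
    def test_monotone_in_window(self, window):
        # enlarging the window can only flip solitary -> not solitary
        mt = _diverge(MT_REF, 0.05, seed=3)
        re_gene, mt_gene, rep = _build_scan_fixture(mt, distance=8000)
        thr = Thresholds(vicinity_bp=window)
        scan = scan_vicinity_for_mtases(re_gene, rep, [re_gene, mt_gene], {"ref": MT_REF}, thr)
        solitary_now = call_solitary(re_gene, scan)
        if window >= 9500:
            assert not solitary_now
        else:
            assert solitary_now


class TestSolitaryCandidates:
    def test_only_incomplete_noncorrupted(self, gene_factory):
        re1 = gene_factory(gene_id="a_re", role=Role.RE, system_id="s1")
        mt1 = gene_factory(gene_id="a_mt", role=Role.MTASE, system_id="s1", start=12_000, end=13_000)
        re2 = gene_factory(gene_id="b_re", role=Role.RE, system_id="s2", start=50_000, end=51_000)
        re3 = gene_factory(
            gene_id="c_re", role=Role.RE, system_id="s3", start=70_000, end=71_000,
            corrupted=True, protein_seq=None,
        )
        systems = build_systems([re1, mt1, re2, re3])
        assert [g.gene_id for g in solitary_candidates(systems)] == ["b_re"]
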