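"""Primer design: Tm model, binding extension, clustering, fragment
planning, primer grammar, workflow choice, protocol rendering."""

import random

import pytest
from Bio.SeqUtils import MeltingTemp as mt

from ggmut import (
    DesignError,
    DnaSequence,
    MutationSpec,
    PAGM9121,
    PAGM22082_CRED,
    ValidationError,
    build_primers,
    choose_workflow,
    cluster_mutations,
    design,
    extend_binding,
    melting_temperature,
    plan_fragments,
    render_protocol,
    reverse_complement,
)
from ggmut.primerdesign import DesignConfig
from ggmut import fixtures


def biopython_tm(seq):
    """Independent nearest-neighbor oracle (same published parameter set
    and conditions, separately implemented)."""
    return mt.Tm_NN(seq, nn_table=mt.DNA_NN3, Na=50, dnac1=500, dnac2=0,
                    saltcorr=5)


class TestMeltingTemperature:
    def test_gc_rich_melts_higher_than_at_rich(self):
        assert melting_temperature("AAAAAAAAAA") < melting_temperature(
            "GCGCGCGCGC"
        )

    def test_agrees_with_independent_oracle(self):
        rng = random.Random(0)
        for _ in range(1000):
            s = "".join(rng.choice("ACGT") for _ in range(rng.randint(12, 40)))
            assert melting_temperature(s) == pytest.approx(
                biopython_tm(s), abs=0.1
            )

    def test_monotone_under_gc_extension(self):
        rng = random.Random(1)
        for _ in range(1000):
            s = "".join(rng.choice("ACGT") for _ in range(15))
            ext = s + rng.choice("GC")
            assert melting_temperature(ext) >= melting_temperature(s) - 1e-9

    @pytest.mark.parametrize("bad", ["ACGTACG", "ACGTNACGTACGT"])
    def test_rejects_short_or_degenerate(self, bad):
        with pytest.raises(ValidationError):
            melting_temperature(bad)


class TestExtendBinding:
    def test_gc_rich_template_needs_shorter_binding(self):
        gc = "GCGGCCGCGGGCCCGCGGCCGCGGGCCCGCGGCC"
        at = "ATTATAATTATATAATTATAATATTATAATATTATAATATTTAT" * 2
        b_gc, _, _ = extend_binding(gc, 0, "forward", 60.0)
        b_at, _, low = extend_binding(at, 0, "forward", 60.0)
        assert len(b_gc) < len(b_at)

    def test_returned_length_is_minimal(self):
        rng = random.Random(2)
        for _ in range(50):
            t = "".join(rng.choice("ACGT") for _ in range(80))
            b, tm, low = extend_binding(t, 0, "forward", 60.0)
            if not low and len(b) > 12:
                assert melting_temperature(b[:-1]) < 60.0
            assert low or tm >= 60.0

    def test_template_exhaustion_is_an_error(self):
        t = "".join("ACGT" for _ in range(20))
        with pytest.raises(DesignError, match="exhausted"):
            extend_binding(t, len(t) - 10, "forward", 60.0)

    def test_low_tm_flag_at_cap(self):
        t = "AT" * 60
        b, tm, low = extend_binding(t, 0, "forward", 60.0)
        assert low and len(b) == 45 and tm < 60.0


class TestClustering:
    def test_multisite_position_geometry_forms_two_clusters(self):
        clusters = cluster_mutations([137, 143, 147, 232, 234], 45)
        assert [list(c) for c in clusters] == [[137, 143, 147], [232, 234]]

    def test_single_and_empty(self):
        assert len(cluster_mutations([42], 45)) == 1
        assert cluster_mutations([], 45) == []

    def test_span_boundary_is_inclusive(self):
        # (16 - 2 + 1) * 3 = 45 -> same cluster; one further -> split
        assert len(cluster_mutations([2, 16], 45)) == 1
        assert len(cluster_mutations([2, 17], 45)) == 2


class TestPlanFragments:
    def test_zero_mutations_wild_type_cloning(self, saturation_cds):
        plan = plan_fragments(saturation_cds, [], PAGM22082_CRED)
        assert plan.n_fragments == 1
        primers = build_primers(plan)
        assert len(primers) == 1 and len(primers[0]) == 2

    def test_one_site_two_fragments(self, saturation_cds):
        plan = plan_fragments(
            saturation_cds, [MutationSpec(137, "saturation", "NDT")],
            PAGM22082_CRED,
        )
        assert plan.n_fragments == 2

    def test_five_sites_three_fragments(self, saturation_cds,
                                        saturation_mutations):
        plan = plan_fragments(saturation_cds, saturation_mutations,
                              PAGM22082_CRED)
        assert plan.n_fragments == 3

    def test_fragment_count_is_cluster_count_plus_one(self, saturation_cds):
        rng = random.Random(3)
        for _ in range(20):
            positions = sorted(rng.sample(range(40, 260), rng.randint(1, 5)))
            if any(b - a < 40 for a, b in zip(positions, positions[1:])):
                continue
            muts = [MutationSpec(p, "saturation", "NDT") for p in positions]
            plan = plan_fragments(saturation_cds, muts, PAGM22082_CRED)
            n_clusters = len(cluster_mutations(positions, 45))
            assert plan.n_fragments == n_clusters + 1

    def test_overhang_set_validity(self, saturation_design):
        ohs = saturation_design.plan.all_overhangs()
        assert len(set(ohs)) == len(ohs)
        rcs = {reverse_complement(o) for o in ohs}
        assert not (rcs & set(ohs))
        assert all(o != reverse_complement(o) for o in ohs)

    def test_vector_overhangs_terminate_the_plan(self, saturation_design):
        frags = saturation_design.plan.fragments
        assert frags[0].left_overhang == "AATG"
        assert frags[-1].right_overhang == "GCTT"

    def test_too_close_clusters_give_short_fragment_error(self, saturation_cds):
        muts = [MutationSpec(100, "saturation", "NDT"),
                MutationSpec(120, "saturation", "NDT")]
        with pytest.raises(DesignError, match="shorter"):
            plan_fragments(saturation_cds, muts, PAGM22082_CRED)


class TestBuildPrimers:
    def test_primer_structural_grammar(self, saturation_design):
        cfg = DesignConfig()
        for p in saturation_design.all_primers:
            assert p.full_sequence == (
                p.padding + p.recognition + p.spacer + p.overhang_as_written
                + p.mutagenic_insert + p.binding
            )
            assert p.padding == cfg.padding
            assert p.recognition == "GGTCTC"  # BsaI design
            assert len(p.spacer) == 1
            assert len(p.overhang) == 4

    def test_saturation_codons_sit_in_insert_not_overhang(
        self, saturation_design
    ):
        inner_fwds = [f for f, r in saturation_design.primers[1:]]
        for p in inner_fwds:
            assert "NDT" in p.mutagenic_insert
            assert all(c in "ACGT" for c in p.overhang)

    def test_intervening_wild_type_codons_carried_verbatim(
        self, saturation_cds, saturation_design
    ):
        # fragment 2 forward spans codons 137..147: the non-mutated codons
        # in between must match the template
        p = saturation_design.primers[1][0]
        frag = saturation_design.plan.fragments[1]
        expect = saturation_design.plan.mutated_cds[
            frag.start: frag.start + len(p.mutagenic_insert)
        ]
        assert p.mutagenic_insert == expect
        wt = saturation_cds.bases[frag.start: frag.start + len(expect)]
        mutated_nt = {
            i for e in saturation_design.plan.edits
            for i in range(e.nt_start, e.nt_end)
        }
        for i, (a, b) in enumerate(zip(expect, wt)):
            if frag.start + i not in mutated_nt:
                assert a == b  # intervening wild-type bases verbatim

    def test_pair_tm_balance(self, saturation_design):
        for f, r in saturation_design.primers:
            assert f.low_tm or f.binding_tm >= 57.0
            assert r.low_tm or r.binding_tm >= 57.0
            if not (f.low_tm or r.low_tm):
                assert abs(f.binding_tm - r.binding_tm) <= 5.0

    def test_bbsi_primer_prefix_layout(self, point_cds):
        """Cloning-vector primers start padding+GAAGAC+2nt spacer+CTCA."""
        res = design(point_cds, [MutationSpec(69, "point", "V")],
                     vector=PAGM9121)
        first_fwd = res.primers[0][0]
        assert first_fwd.full_sequence.startswith("TT" + "GAAGAC" + "AA" + "CTCA")

    def test_point_mutation_encoded_in_overhang_when_possible(self, point_cds):
        res = design(point_cds, [MutationSpec(69, "point", "V")],
                     vector=PAGM9121)
        edit = next(e for e in res.plan.edits if e.mode == "point")
        frag = next(
            f for f in res.plan.fragments if edit in f.edits_on_forward
        )
        carrier = res.primers[frag.index][0]
        combined = carrier.overhang + carrier.mutagenic_insert
        assert edit.new_codon in combined
        # the mutated codon overlaps the junction overhang window itself
        assert edit.new_codon in frag.left_overhang + carrier.mutagenic_insert


class TestWorkflowAndProtocol:
    @pytest.mark.parametrize(
        "n,expected",
        [(1, "one_step"), (2, "one_step"), (3, "one_step"),
         (4, "two_step"), (5, "two_step"), (8, "two_step")],
    )
    def test_one_step_iff_three_or_fewer_fragments(self, n, expected):
        assert choose_workflow(n) == expected

    def test_protocol_contains_every_primer_and_is_deterministic(
        self, saturation_design
    ):
        text = saturation_design.protocol_text
        for p in saturation_design.all_primers:
            assert p.full_sequence in text
        assert render_protocol(saturation_design) == render_protocol(
            saturation_design
        )

    def test_protocol_names_vector_and_enzyme(self, saturation_design,
                                              point_cds):
        assert "BsaI" in saturation_design.protocol_text
        assert "pAGM22082_CRed" in saturation_design.protocol_text
        res = design(point_cds, [MutationSpec(69, "point", "V")],
                     vector=PAGM9121)
        assert "BbsI" in res.protocol_text
        assert "pAGM9121" in res.protocol_text


class TestDesignGuards:
    def test_saturation_on_undomesticated_gene_refused(self, point_cds):
        with pytest.raises(DesignError, match="domesticate"):
            design(point_cds, [MutationSpec(69, "saturation", "NDT")],
                   vector=PAGM9121)

    def test_saturation_on_undomesticated_gene_forced(self, point_cds):
        cfg = DesignConfig(force_undomesticated=True)
        res = design(point_cds, [MutationSpec(69, "saturation", "NDT")],
                     vector=PAGM9121, config=cfg)
        assert any(e.mode == "silent_fix" for e in res.plan.edits)

    def test_terminal_positions_rejected_by_default(self, saturation_cds):
        with pytest.raises(ValidationError, match="range"):
            design(saturation_cds, [MutationSpec(1, "point", "V")])

    def test_duplicate_positions_rejected(self, saturation_cds):
        muts = [MutationSpec(137, "saturation", "NDT")] * 2
        with pytest.raises(ValidationError, match="duplicate"):
            design(saturation_cds, muts)

    def test_point_mutation_forming_a_site_is_repaired_silently(self):
        """Every proline codon after a GGA-AGA context completes a BbsI
        site (GGAAGA + CC... -> GAAGAC); the engine must accept the
        mutation and remove the site with a silent fix next door."""
        from ggmut import translate, verify_design
        from ggmut.domestication import scan_sites as scan
        rng = random.Random(6)
        while True:
            cds = fixtures.random_cds(150, rng)
            bases = cds.bases[:180] + "GGAAGATTG" + cds.bases[189:]
            try:
                cds = DnaSequence(bases, is_cds=True)
            except Exception:
                continue
            if scan(cds) == []:  # no site until proline closes GAAGA+C
                break
        target_pos = 63  # the TTG codon at nt 186
        res = design(cds, [MutationSpec(target_pos, "point", "P")], PAGM9121)
        mutated = res.plan.mutated_cds
        assert scan(mutated) == []
        assert translate(mutated)[target_pos - 1] == "P"
        # all other residues unchanged
        wt, mu = translate(cds), translate(mutated)
        assert all(a == b for i, (a, b) in enumerate(zip(wt, mu))
                   if i != target_pos - 1)
        assert verify_design(cds, res).is_seamless
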