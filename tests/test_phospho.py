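"""Phospho-site merging, mutant construction and net-charge arithmetic."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ieskit as ik
from ieskit.phospho import (
    PhosphoSite,
    PhosphoSiteSet,
    pdd1_like,
    pdd1_mutant_series,
)


@pytest.fixture(scope="module")
def fixture_protein():
    return pdd1_like()


@pytest.fixture(scope="module")
def merged(fixture_protein):
    _, a, b = fixture_protein
    return ik.merge_site_sets(a, b)


class TestSiteMerge:
    def test_two_study_merge_cardinality(self, fixture_protein):
        """31 sites merged with 10 sites of which 2 are novel -> 33 total."""
        _, a, b = fixture_protein
        assert len(a) == 31 and len(b) == 10
        union = ik.merge_site_sets(a, b)
        assert len(union) == 33
        novel = set(b.positions) - set(a.positions)
        assert len(novel) == 2

    def test_idempotence(self, fixture_protein):
        _, a, _ = fixture_protein
        assert ik.merge_site_sets(a, a).positions == a.positions

    def test_disjoint_sets_add(self):
        a = PhosphoSiteSet.build([(1, "S"), (3, "T"), (5, "S")], "x")
        b = PhosphoSiteSet.build([(2, "S"), (4, "T"), (6, "S"), (8, "T")], "y")
        assert len(ik.merge_site_sets(a, b)) == 7

    def test_conflicting_residue_is_hard_error(self):
        a = PhosphoSiteSet.build([(5, "S")], "x")
        b = PhosphoSiteSet.build([(5, "T")], "y")
        with pytest.raises(ValueError, match="conflicting"):
            ik.merge_site_sets(a, b)

    def test_provenance_merged_at_shared_positions(self, merged):
        shared = [s for s in merged.sites if len(s.provenance) == 2]
        assert len(shared) == 8

    @given(
        pa=st.sets(st.integers(1, 60), min_size=1, max_size=30),
        pb=st.sets(st.integers(1, 60), min_size=1, max_size=30),
    )
    def test_inclusion_exclusion(self, pa, pb):
        """|union| = |a| + |b| - |a & b| for random site sets."""
        a = PhosphoSiteSet.build([(p, "S") for p in pa], "a")
        b = PhosphoSiteSet.build([(p, "S") for p in pb], "b")
        assert len(ik.merge_site_sets(a, b)) == len(pa) + len(pb) - len(pa & pb)

    def test_tsv_roundtrip(self, tmp_path, merged):
        merged.to_tsv(tmp_path / "sites.tsv")
        back = PhosphoSiteSet.from_tsv(tmp_path / "sites.tsv")
        assert back.positions == merged.positions


class TestMutants:
    def test_mim22_has_22_glu_at_selected_sites(self, fixture_protein, merged):
        protein, _, _ = fixture_protein
        spec = ik.mim_spec(protein, merged, 22)
        mut = ik.apply_mutations(protein, spec)
        assert len(mut) == len(protein)
        changed = [p for p, _, _ in spec.substitutions]
        assert len(changed) == 22
        assert all(mut.residue(p) == "E" for p in changed)
        assert all(protein.residue(p) in "ST" for p in changed)

    def test_ins6k_adds_six_lysines(self, fixture_protein, merged):
        protein, _, _ = fixture_protein
        series = pdd1_mutant_series(protein, merged)
        mut = ik.apply_mutations(protein, series["MIM22+Ins6K"])
        assert len(mut) == len(protein) + 6

    def test_empty_spec_is_identity(self, fixture_protein):
        protein, _, _ = fixture_protein
        mut = ik.apply_mutations(protein, ik.MutantSpec(name="noop"))
        assert mut.sequence == protein.sequence
        assert dict(mut.regions) == dict(protein.regions)

    def test_wrong_from_residue_names_position(self, fixture_protein):
        protein, _, _ = fixture_protein
        pos = 1
        wrong = "A" if protein.residue(pos) != "A" else "G"
        spec = ik.MutantSpec(name="bad", substitutions=((pos, wrong, "E"),))
        with pytest.raises(ValueError, match=str(pos)):
            ik.apply_mutations(protein, spec)

    def test_insertion_shifts_downstream_regions(self, fixture_protein):
        protein, _, _ = fixture_protein
        spec = ik.MutantSpec(name="ins", insertions=((150, "KKK"),))
        mut = ik.apply_mutations(protein, spec)
        s0, e0 = protein.regions["HNG1"]
        assert mut.regions["HNG1"] == (s0, e0 + 3)  # insertion inside HNG1
        assert mut.regions["CSD"] == tuple(x + 3 for x in protein.regions["CSD"])
        assert mut.regions["NT"] == protein.regions["NT"]


class TestNetCharge:
    REGIONS = ("NT", "HNG1", "HNG2")

    def test_report_sums_its_breakdown(self, fixture_protein):
        protein, _, _ = fixture_protein
        rep = ik.net_charge(protein, self.REGIONS)
        assert rep.net_charge == pytest.approx(rep.breakdown["charge"].sum())

    def test_mim22_shifts_charge_by_minus_22(self, fixture_protein, merged):
        protein, _, _ = fixture_protein
        mut = ik.apply_mutations(protein, ik.mim_spec(protein, merged, 22))
        dq = (
            ik.net_charge(mut, self.REGIONS).net_charge
            - ik.net_charge(protein, self.REGIONS).net_charge
        )
        assert dq == -22

    def test_lys_variants_shift_charge_by_plus_6(self, fixture_protein, merged):
        protein, _, _ = fixture_protein
        series = pdd1_mutant_series(protein, merged)
        q22 = ik.net_charge(
            ik.apply_mutations(protein, series["MIM22"]), self.REGIONS
        ).net_charge
        for name in ("MIM22+Ins6K", "MIM22+Sub6K"):
            q = ik.net_charge(
                ik.apply_mutations(protein, series[name]), self.REGIONS
            ).net_charge
            assert q - q22 == +6

    def test_full_phosphorylation_at_minus_2_per_site(self, fixture_protein, merged):
        """22 phosphorylated sites at -2 each shift the region charge by -44."""
        protein, _, _ = fixture_protein
        allowed = set(protein.region_positions(self.REGIONS))
        sites22 = merged.restrict(sorted(p for p in merged.positions if p in allowed)[:22])
        q_p = ik.net_charge(protein, self.REGIONS, phospho=sites22).net_charge
        q_0 = ik.net_charge(protein, self.REGIONS).net_charge
        assert q_p - q_0 == -44

    def test_charge_ordering_of_series(self, fixture_protein, merged):
        """WT > MIM10 > MIM14 > MIM18 > MIM22;
        MIM22+Ins6K = MIM22+Sub6K = MIM22 + 6."""
        protein, _, _ = fixture_protein
        series = pdd1_mutant_series(protein, merged)
        rank = ik.charge_rank(protein, list(series.values()), region=self.REGIONS)
        q = rank.set_index("name")["net_charge"]
        assert q["WT"] > q["MIM10"] > q["MIM14"] > q["MIM18"] > q["MIM22"]
        assert q["MIM10"] - q["WT"] == -10
        assert q["MIM22"] - q["WT"] == -22
        assert q["MIM22+Ins6K"] == q["MIM22+Sub6K"] == q["MIM22"] + 6

    def test_charge_invariant_to_edits_outside_region(self, fixture_protein):
        protein, _, _ = fixture_protein
        s, e = protein.regions["CSD"]
        pos = next(p for p in range(s, e + 1) if protein.residue(p) not in "DEKR")
        spec = ik.MutantSpec(
            name="csd_edit", substitutions=((pos, protein.residue(pos), "K"),)
        )
        mut = ik.apply_mutations(protein, spec)
        assert (
            ik.net_charge(mut, self.REGIONS).net_charge
            == ik.net_charge(protein, self.REGIONS).net_charge
        )

    def test_charge_additivity(self, fixture_protein, merged):
        """Non-interacting edit sets contribute additively to the charge shift."""
        protein, _, _ = fixture_protein
        s1 = ik.mim_spec(protein, merged, 10)
        s2 = ik.MutantSpec(name="ins", insertions=((350, "KK"),))
        combined = ik.MutantSpec(
            name="both", substitutions=s1.substitutions, insertions=s2.insertions
        )
        q0 = ik.net_charge(protein, self.REGIONS).net_charge
        d1 = ik.net_charge(ik.apply_mutations(protein, s1), self.REGIONS).net_charge - q0
        d2 = ik.net_charge(ik.apply_mutations(protein, s2), self.REGIONS).net_charge - q0
        dc = ik.net_charge(ik.apply_mutations(protein, combined), self.REGIONS).net_charge - q0
        assert dc == d1 + d2

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            ik.ProteinRecord(sequence="ACDX")


def test_fasta_input(tmp_path, fixture_protein):
    protein, _, _ = fixture_protein
    path = tmp_path / "p.fa"
    path.write_text(f">pdd1_like\n{protein.sequence}\n")
    back = ik.ProteinRecord.from_fasta(path, regions=dict(protein.regions))
    assert back.sequence == protein.sequence
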