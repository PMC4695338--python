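"""Counting rules and the retention index: floors, ratios, invariances."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import ieskit as ik
from ieskit.genome import Interval
from ieskit.reads import PlacedReadSet
from tests.conftest import newmac_coverage


def _readset(records, channel="WGS"):
    chrom, start, end = zip(*records)
    n = len(records)
    return PlacedReadSet(
        chrom=np.array(chrom, dtype="U32"),
        start=np.array(start, dtype=np.int64),
        end=np.array(end, dtype=np.int64),
        source=np.zeros(n, dtype=np.uint8),
        channel=channel,
    )


ANN = [
    Interval("chr1", 0, 1000, "MDS", "MDS_1"),
    Interval("chr1", 1000, 2000, "IES", "IES_1"),
    Interval("chr1", 2000, 3000, "MDS", "MDS_2"),
]


class TestMidpointAssignment:
    def test_read_inside_ies_counts_once(self):
        cov = ik.count_reads(_readset([("chr1", 1200, 1250)]), ANN)
        assert cov.counts().to_dict() == {"MDS_1": 0, "IES_1": 1, "MDS_2": 0}

    def test_straddling_read_goes_to_midpoint_interval(self):
        # read 980-1040: midpoint 1010 lies in the IES
        cov = ik.count_reads(_readset([("chr1", 980, 1040)]), ANN)
        assert cov.counts()["IES_1"] == 1 and cov.counts()["MDS_1"] == 0

    def test_unknown_chromosome_skipped_and_logged(self):
        cov = ik.count_reads(_readset([("chrX", 0, 50), ("chr1", 10, 60)]), ANN)
        assert cov.n_skipped == 1 and cov.total_reads == 1

    def test_uniform_reads_partition_at_genome_fraction(self, small_genome, small_params):
        """Law of large numbers: IES-assigned fraction tends to the IES
        genome fraction for uniform reads."""
        reads = ik.simulate_wgs(small_genome, small_params, "MIC")
        cov = ik.count_reads(reads, small_genome.intervals)
        ies_frac = (
            cov.data.loc[cov.data["kind"] == "IES", "count"].sum() / cov.total_reads
        )
        assert ies_frac == pytest.approx(small_genome.ies_fraction, rel=0.02)
        # midpoint rule partitions counts exactly
        assert cov.data["count"].sum() == cov.total_reads


class TestRetentionIndex:
    def test_self_ratio_is_one(self, small_genome, small_params):
        reads = ik.simulate_wgs(small_genome, small_params, "MIC")
        cov = ik.count_reads(reads, small_genome.intervals)
        table = ik.retention_index(cov, cov)
        assert np.allclose(table.ri.to_numpy(), 1.0)

    def test_complete_elimination_zero_contamination_all_zero(
        self, small_genome, small_params
    ):
        """The theoretical WT limit: every RI exactly 0 when c=0."""
        mic = ik.count_reads(
            ik.simulate_wgs(small_genome, small_params, "MIC"), small_genome.intervals
        )
        new = newmac_coverage(small_genome, small_params, 0.0, 0.0, "clean")
        table = ik.retention_index(new, mic)
        assert (table.ri.to_numpy() == 0.0).all()
        assert table.n_dropped == 0

    @pytest.mark.parametrize("c", [0.02, 0.05, 0.10])
    def test_contamination_floor_recovers_c(self, small_genome, small_params, c):
        """Median RI of a complete-elimination sample recovers the
        contamination fraction within 20% relative error."""
        mic = ik.count_reads(
            ik.simulate_wgs(small_genome, small_params, "MIC"), small_genome.intervals
        )
        new = newmac_coverage(small_genome, small_params, 0.0, c, f"wt_c{c}")
        med = ik.summarize_ri(ik.retention_index(new, mic))["median"]
        assert abs(med - c) / c < 0.20

    def test_ri_monotone_in_retained_fraction(self, small_genome, small_params):
        """Median RI increases with the retained fraction at fixed c."""
        mic = ik.count_reads(
            ik.simulate_wgs(small_genome, small_params, "MIC"), small_genome.intervals
        )
        medians = [
            ik.summarize_ri(
                ik.retention_index(
                    newmac_coverage(small_genome, small_params, r, 0.05, f"r{r}"), mic
                )
            )["median"]
            for r in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert all(a < b for a, b in zip(medians, medians[1:]))
        # mixture law: expected RI ~ c + (1-c) r / (1 - f(1-r)) >= c
        assert all(m >= 0.04 for m in medians)

    def test_scale_invariance(self, small_genome, small_params):
        """Multiplying one sample's raw counts by a constant leaves RI unchanged."""
        mic = ik.count_reads(
            ik.simulate_wgs(small_genome, small_params, "MIC"), small_genome.intervals
        )
        new = newmac_coverage(small_genome, small_params, 1.0, 0.05, "scaled")
        base = ik.retention_index(new, mic).ri
        boosted = ik.CoverageTable(
            data=new.data.assign(count=new.data["count"] * 7),
            sample=new.sample,
            total_reads=new.total_reads * 7,
        )
        assert np.allclose(ik.retention_index(boosted, mic).ri.to_numpy(), base.to_numpy())

    def test_per_bp_mode_matches_count_mode(self, small_genome, small_params):
        """Length normalization cancels in the ratio."""
        mic = ik.count_reads(
            ik.simulate_wgs(small_genome, small_params, "MIC"), small_genome.intervals
        )
        new = newmac_coverage(small_genome, small_params, 0.5, 0.05, "pb")
        a = ik.retention_index(new, mic, per_bp=False).ri.to_numpy()
        b = ik.retention_index(new, mic, per_bp=True).ri.to_numpy()
        assert np.allclose(a, b)

    def test_zero_reference_dropped_not_infinite(self):
        cov_new = ik.count_reads(_readset([("chr1", 1100, 1150)]), ANN)
        cov_mic = ik.count_reads(_readset([("chr1", 100, 150)]), ANN)
        table = ik.retention_index(cov_new, cov_mic)
        assert table.n_dropped == 1
        assert len(table.data) == 0

    def test_annotation_mismatch_is_hard_error(self):
        cov_a = ik.count_reads(_readset([("chr1", 10, 60)]), ANN)
        other = [Interval("chr1", 0, 3000, "MDS", "MDS_only")]
        cov_b = ik.count_reads(_readset([("chr1", 10, 60)]), other)
        with pytest.raises(ValueError, match="mismatch"):
            ik.retention_index(cov_a, cov_b)

    def test_reference_self_consistency(self, small_genome, small_params):
        """RI of one MIC simulation against an independent MIC simulation
        has median 1 within sampling error."""
        mic1 = ik.count_reads(
            ik.simulate_wgs(small_genome, small_params, "MIC", label="mic1"),
            small_genome.intervals,
        )
        mic2 = ik.count_reads(
            ik.simulate_wgs(small_genome, small_params, "MIC", label="mic2"),
            small_genome.intervals,
        )
        med = ik.summarize_ri(ik.retention_index(mic1, mic2))["median"]
        assert med == pytest.approx(1.0, abs=0.05)


class TestSummary:
    def test_median_of_zeros(self):
        table = ik.RetentionTable(
            data=pd.DataFrame(
                {"id": ["a", "b", "c"], "chrom": "chr1", "start": 0, "end": 1,
                 "length": 1, "n_newmac": 0, "n_mic": 1, "ri": [0.0, 0.0, 0.0]}
            ),
            numerator="x", reference="y",
        )
        s = ik.summarize_ri(table)
        assert s["median"] == 0.0 and s["frac_below_0.1"] == 1.0

    def test_empty_table_errors(self):
        table = ik.RetentionTable(
            data=pd.DataFrame(columns=["id", "ri"]), numerator="x", reference="y"
        )
        with pytest.raises(ValueError):
            ik.summarize_ri(table)
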