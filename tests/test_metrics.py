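"""URE/dURE, 3'RPM, pUGA, A-site occupancies, correlations, contrasts."""

import numpy as np
import pandas as pd
import pytest

import ribosec as rs
from ribosec.metrics import MetricsError, ure_from_counts

from conftest import run_simulation


def make_assignments(ann, codons, sample="s1", size="bRPF", frames=None):
    """Hand-built assignment table rows with in-CDS P-sites at ``codons``."""
    codons = np.asarray(codons, dtype=float)
    frames = np.zeros(len(codons)) if frames is None else np.asarray(frames)
    n_codons = ann.n_codons
    return pd.DataFrame({
        "transcript_id": ann.transcript_id,
        "gene": ann.gene,
        "sample_id": sample,
        "read_length": 28 if size == "bRPF" else 21,
        "size_class": size,
        "five_prime": ann.cds_start + 3 * codons - 12,
        "psite_nt": ann.cds_start + 3 * codons,
        "in_cds": True,
        "psite_codon": codons,
        "asite_codon": np.where(codons + 1 <= n_codons - 1,
                                codons + 1, np.nan),
        "frame": frames,
    })


@pytest.fixture()
def ure_annotation():
    # 453 codons incl. stop; UGA at 301: 5' region codons 1..300 (300),
    # 3' region codons 302..451 (150)
    return rs.TranscriptAnnotation("tx", "G", 1429, 10, 1369, (301,))


class TestUre:
    def test_uniform_density_gives_one(self, ure_annotation):
        ann = ure_annotation
        codons = list(range(1, 301)) + list(range(302, 452))
        df = make_assignments(ann, codons)
        assert rs.ure(df, ann) == pytest.approx(1.0)

    def test_zero_3prime_reads_give_zero(self, ure_annotation):
        df = make_assignments(ure_annotation, range(1, 301))
        assert rs.ure(df, ure_annotation) == 0.0

    def test_hand_counted_example(self, ure_annotation):
        ann = ure_annotation
        rng = np.random.default_rng(0)
        five = rng.integers(1, 301, size=600)     # 600 reads / 300 codons
        three = rng.integers(302, 452, size=150)  # 150 reads / 150 codons
        df = make_assignments(ann, np.concatenate([five, three]))
        assert rs.ure(df, ann) == pytest.approx(0.5)

    def test_uga_codon_belongs_to_neither_region(self, ure_annotation):
        ann = ure_annotation
        df = make_assignments(ann, [301] * 50 + [100, 400])
        rc = rs.region_counts(df, ann)
        assert rc["counts_uga"] == 50
        assert rc["counts_5prime"] == 1 and rc["counts_3prime"] == 1

    def test_undefined_when_no_5prime_reads(self, ure_annotation):
        df = make_assignments(ure_annotation, [400, 410])
        assert np.isnan(rs.ure(df, ure_annotation))

    def test_zero_length_region_is_undefined(self):
        assert np.isnan(ure_from_counts(10, 0, 0, 50))


class TestDeltaUre:
    def test_quotients(self):
        assert rs.delta_ure(1.0, 1.0) == pytest.approx(1.0)
        assert rs.delta_ure(0.1, 0.5) == pytest.approx(0.2)

    def test_control_zero_or_nan_never_gives_infinity(self):
        assert np.isnan(rs.delta_ure(0.5, 0.0))
        assert np.isnan(rs.delta_ure(float("nan"), 0.5))

    def test_invariant_to_global_count_rescaling(self, ure_annotation):
        ann = ure_annotation
        rng = np.random.default_rng(1)
        codons = rng.integers(1, 452, size=400)
        df = make_assignments(ann, codons)
        scaled = pd.concat([df] * 7, ignore_index=True)  # counts x7
        assert rs.ure(scaled, ann) == pytest.approx(rs.ure(df, ann))
        assert rs.delta_ure(rs.ure(scaled, ann), 0.8) == \
            pytest.approx(rs.delta_ure(rs.ure(df, ann), 0.8))


class TestRpmMetrics:
    def test_three_prime_rpm_value(self, ure_annotation):
        ann = ure_annotation
        df = make_assignments(ann, [310] * 20)
        assert rs.three_prime_rpm(df, ann, 4_000_000) == pytest.approx(5.0)

    def test_puga_value(self, ure_annotation):
        df = make_assignments(ure_annotation, [301] * 10)
        assert rs.puga(df, ure_annotation, 2_000_000) == pytest.approx(5.0)

    def test_asite_occupancy_by_class(self, ure_annotation):
        ann = ure_annotation
        df = pd.concat([make_assignments(ann, [300] * 6, size="bRPF"),
                        make_assignments(ann, [300] * 3, size="sRPF")])
        assert rs.asite_uga_occupancy(df, ann, 3_000_000, "bRPF") == \
            pytest.approx(2.0)
        assert rs.asite_uga_occupancy(df, ann, 3_000_000, "sRPF") == \
            pytest.approx(1.0)
        with pytest.raises(MetricsError):
            rs.asite_uga_occupancy(df, ann, 3_000_000, "big")

    def test_per_mrna_normalization(self):
        assert rs.three_prime_rpm_per_mrna(5.0, 2.0) == pytest.approx(2.5)
        assert np.isnan(rs.three_prime_rpm_per_mrna(5.0, 0.0))

    def test_nmd_depletion_cancels_in_per_mrna_measure(self):
        """Halving mRNA at fixed readthrough halves 3'RPM but leaves
        3'RPM/mRNA unchanged within sampling error."""
        def run(depletion, seed):
            genes = [rs.GeneParams(f"G{i}", 101, 50, base_density=40.0,
                                   readthrough=0.6, nmd_depletion=depletion,
                                   mrna_level=1000.0) for i in range(8)]
            anns, res = run_simulation(genes, seed=seed)
            df = rs.assignment_table(res.raw_frame(), anns)
            total = float(rs.mapped_totals(df).iloc[0])
            t3 = np.mean([rs.three_prime_rpm(df, anns[g.name], 1e6)
                          for g in genes])
            mrna = 1000.0 * depletion  # expected CPM-scale abundance
            return t3, t3 / mrna

        t3_full, norm_full = run(1.0, 21)
        t3_half, norm_half = run(0.5, 22)
        assert t3_half / t3_full == pytest.approx(0.5, rel=0.1)
        assert norm_half / norm_full == pytest.approx(1.0, rel=0.1)


class TestMultiSecRegions:
    def test_regions_bounded_by_neighboring_ugas(self):
        ann = rs.TranscriptAnnotation("t", "g", 400, 10, 310, (20, 60))
        five1, uga1, three1 = rs.sec_regions(ann, 20)
        assert (five1.start, five1.stop) == (1, 20) and uga1 == 20
        assert (three1.start, three1.stop) == (21, 60)
        five2, uga2, three2 = rs.sec_regions(ann, 60)
        assert (five2.start, five2.stop) == (21, 60)
        assert (three2.start, three2.stop) == (61, ann.last_sense_codon + 1)
        with pytest.raises(MetricsError):
            rs.sec_regions(ann)  # ambiguous without uga_index


class TestCorrelate:
    def test_exact_correlations(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        assert rs.correlate(x, x) == pytest.approx(1.0)
        assert rs.correlate(x, 1 / x) == pytest.approx(-1.0)

    def test_too_few_points_is_nan(self):
        assert np.isnan(rs.correlate([1.0, 2.0], [1.0, 2.0]))

    def test_shared_readthrough_drives_puga_3prime_rpm_correlation(self):
        """When one per-gene readthrough drives both pUGA and 3'RPM, the two
        metrics correlate strongly across genes."""
        rng = np.random.default_rng(13)
        genes = [rs.GeneParams(f"G{i}", 101, 50, base_density=30.0,
                               readthrough=float(r))
                 for i, r in enumerate(rng.uniform(0.05, 1.0, 20))]
        anns, res = run_simulation(genes, seed=14)
        df = rs.assignment_table(res.raw_frame(), anns)
        total = float(rs.mapped_totals(df).iloc[0])
        pugas = [rs.puga(df, anns[g.name], total) for g in genes]
        t3s = [rs.three_prime_rpm(df, anns[g.name], total) for g in genes]
        assert rs.correlate(pugas, t3s) > 0.9


class TestRecodingTableOracle:
    def test_region_counts_match_naive_loop_on_small_fixture(self):
        genes = [rs.GeneParams(f"G{i}", 60, 25, base_density=1.5,
                               readthrough=0.6, stall_weight=0.5)
                 for i in range(5)]
        anns, res = run_simulation(genes, seed=15, jitter=0.1)
        df = rs.assignment_table(res.raw_frame(), anns)
        assert len(df) <= 1000
        rec = rs.recoding_table(df, anns)
        for g in genes:
            ann = anns[g.name]
            u = 25
            n5 = n3 = nu = npu = nab = nas = 0
            for row in df.itertuples(index=False):
                if row.transcript_id != g.name or not row.in_cds:
                    continue
                c = row.psite_codon
                if 1 <= c < u:
                    n5 += 1
                elif c == u:
                    nu += 1
                    npu += 1
                elif u < c <= ann.last_sense_codon:
                    n3 += 1
                if row.asite_codon == u:
                    if row.size_class == "bRPF":
                        nab += 1
                    else:
                        nas += 1
            got = rec[(rec.gene == g.name)
                      & (rec.sample_id == res.sample_id)].iloc[0]
            total = float(rs.mapped_totals(df).iloc[0])
            assert got["counts_5prime"] == n5
            assert got["counts_3prime"] == n3
            assert got["counts_uga"] == nu
            assert got["puga_rpm"] == pytest.approx(npu * 1e6 / total)
            assert got["asite_uga_rpm_b"] == pytest.approx(nab * 1e6 / total)
            assert got["asite_uga_rpm_s"] == pytest.approx(nas * 1e6 / total)


class TestCompareConditions:
    @staticmethod
    def recoding_from_values(values):
        rows = []
        for gene, per_sample in values.items():
            for sample, v in per_sample.items():
                rows.append({"gene": gene, "uga_index": 10,
                             "sample_id": sample, "ure": v})
        return pd.DataFrame(rows)

    CONDITIONS = {"m1": "mut", "m2": "mut", "c1": "ctl", "c2": "ctl"}

    def test_identical_values_give_p_one(self):
        rec = self.recoding_from_values(
            {"G1": {"m1": 2.0, "m2": 2.0, "c1": 2.0, "c2": 2.0}})
        out = rs.compare_conditions(rec, self.CONDITIONS, "ure")
        assert out.loc[0, "p_value"] == 1.0

    def test_clear_shift_yields_small_q(self):
        values = {f"G{i}": {"m1": 1.0, "m2": 1.01, "c1": 2.0, "c2": 2.01}
                  for i in range(5)}
        out = rs.compare_conditions(self.recoding_from_values(values),
                                    self.CONDITIONS, "ure")
        assert (out["q_value"] < 0.05).all()
        assert out["fold_change"].iloc[0] == pytest.approx(0.5, rel=0.02)
        assert out["delta_ure"].iloc[0] == pytest.approx(0.5, rel=0.02)

    def test_single_replicate_reports_fold_change_without_p(self):
        rec = self.recoding_from_values(
            {"G1": {"m1": 1.0, "c1": 2.0}})
        out = rs.compare_conditions(rec, {"m1": "mut", "c1": "ctl"}, "ure")
        assert np.isnan(out.loc[0, "p_value"])
        assert out.loc[0, "fold_change"] == pytest.approx(0.5)
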