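"""cis instrument selection: the five filters and strength statistics."""

import numpy as np
import pytest

from conftest import make_record
from pqtlmr.instruments import (
    GeneAnnotation,
    InstrumentConfig,
    build_instruments,
    filter_cis,
    filter_mhc,
    filter_significant,
    ld_clump,
    read_ld_matrix,
    snp_strength,
    write_ld_matrix,
)

GENE = GeneAnnotation("GENE1", "P1", "1", 50_000_000)


class TestSignificance:
    def test_strict_inequality(self):
        records = [make_record(snp=f"rs{i}", pval=p) for i, p in enumerate([1e-9, 5e-8, 4e-8])]
        kept = filter_significant(records, 5e-8)
        assert sorted(r.pval for r in kept) == [1e-9, 4e-8]

    def test_empty_input(self):
        assert filter_significant([], 5e-8) == []

    def test_threshold_one_keeps_all(self):
        records = [make_record(pval=0.99), make_record(pval=0.5)]
        assert filter_significant(records, 1.0) == records


class TestMhc:
    @pytest.mark.parametrize(
        "chrom,pos,kept",
        [
            ("6", 30_000_000, False),
            ("6", 25_999_999, True),
            ("6", 26_000_000, False),  # inclusive start
            ("6", 34_000_000, False),  # inclusive end
            ("6", 34_000_001, True),
            ("7", 30_000_000, True),
        ],
    )
    def test_boundaries(self, chrom, pos, kept):
        record = make_record(chrom=chrom, pos=pos)
        assert (record in filter_mhc([record])) is kept


class TestCis:
    @pytest.mark.parametrize(
        "chrom,offset,kept",
        [
            ("1", 1_000_000, True),   # inclusive window edge
            ("1", -1_000_000, True),
            ("1", 1_000_001, False),
            ("2", 0, False),          # wrong chromosome
        ],
    )
    def test_window(self, chrom, offset, kept):
        record = make_record(chrom=chrom, pos=GENE.tss_pos + offset)
        assert (record in filter_cis([record], GENE)) is kept


class TestClump:
    def test_correlated_pair_keeps_most_significant(self):
        records = [
            make_record(snp="rs1", pos=100, pval=1e-20),
            make_record(snp="rs2", pos=200, pval=1e-9),
        ]
        ld = np.array([[1.0, np.sqrt(0.5)], [np.sqrt(0.5), 1.0]])
        assert [r.snp_id for r in ld_clump(records, ld)] == ["rs1"]

    def test_below_threshold_both_survive(self):
        records = [
            make_record(snp="rs1", pos=100, pval=1e-20),
            make_record(snp="rs2", pos=200, pval=1e-9),
        ]
        r = np.sqrt(0.0005)
        ld = np.array([[1.0, r], [r, 1.0]])
        assert len(ld_clump(records, ld)) == 2

    def test_tie_break_on_position(self):
        records = [
            make_record(snp="rs_late", pos=500, pval=1e-10),
            make_record(snp="rs_early", pos=100, pval=1e-10),
        ]
        ld = np.array([[1.0, 0.95], [0.95, 1.0]])
        assert [r.snp_id for r in ld_clump(records, ld)] == ["rs_early"]

    def test_dimension_mismatch_fatal(self):
        with pytest.raises(ValueError, match="shape"):
            ld_clump([make_record()], np.eye(2))

    def test_output_pairwise_below_threshold(self, rng):
        """Survivors are pairwise r² < threshold, assertable on the LD matrix."""
        m = 30
        rho = 0.8
        ld = rho ** np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
        records = [
            make_record(snp=f"rs{i}", pos=1000 + i, pval=float(rng.uniform(1e-12, 1e-4)))
            for i in range(m)
        ]
        kept = ld_clump(records, ld, r2_threshold=0.01)
        idx = [int(r.snp_id[2:]) for r in kept]
        for a in idx:
            for b in idx:
                if a != b:
                    assert ld[a, b] ** 2 < 0.01


class TestStrength:
    def test_null_effect(self):
        pve, f = snp_strength(make_record(beta=0.0))
        assert pve == 0.0 and f == 0.0

    def test_known_values(self):
        pve, f = snp_strength(make_record(beta=0.1, se=0.01, n=10_000))
        assert pve == pytest.approx(0.1**2 / (0.1**2 + 10_000 * 0.01**2), rel=1e-12)
        assert pve == pytest.approx(0.009901, abs=1e-6)
        assert f == pytest.approx(99.98, abs=0.02)

    def test_monotone_in_abs_beta(self):
        fs = [snp_strength(make_record(beta=b))[1] for b in (0.01, 0.05, 0.2, 1.0)]
        assert fs == sorted(fs)

    def test_pve_f_identity(self, rng):
        for _ in range(50):
            rec = make_record(beta=rng.normal(), se=float(rng.uniform(0.001, 1)),
                              n=int(rng.integers(10, 100_000)))
            pve, f = snp_strength(rec)
            assert f == pytest.approx(pve * (rec.n - 2) / (1 - pve), abs=1e-12)

    def test_eaf_variant(self):
        rec = make_record(beta=0.3, eaf=0.2)
        pve, _ = snp_strength(rec, method="eaf")
        assert pve == pytest.approx(2 * 0.2 * 0.8 * 0.09, rel=1e-12)


class TestBuildInstruments:
    def _region(self):
        """One strong causal cis SNP and 5 LD proxies (r = 0.9 with the index)."""
        pos0 = GENE.tss_pos
        records = [
            make_record(snp="rs_index", pos=pos0, beta=0.3, se=0.01, pval=1e-60, n=10_000)
        ]
        for i in range(5):
            records.append(
                make_record(snp=f"rs_proxy{i}", pos=pos0 + 1000 * (i + 1),
                            beta=0.27, se=0.01, pval=1e-50, n=10_000)
            )
        ld = np.full((6, 6), 0.81)
        np.fill_diagonal(ld, 1.0)
        ld[0, 1:] = ld[1:, 0] = 0.9
        ids = [r.snp_id for r in records]
        return records, ld, ids

    def test_only_index_snp_survives(self):
        records, ld, ids = self._region()
        iv = build_instruments(records, GENE, ld, ids, InstrumentConfig())
        assert iv.snp_ids == ["rs_index"]
        assert iv.provenance == {"input": 6, "significant": 6, "mhc": 6, "cis": 6,
                                 "clump": 1, "strength": 1}

    def test_no_significant_snps_gives_empty_set(self):
        records = [make_record(snp=f"rs{i}", pval=1e-6) for i in range(3)]
        iv = build_instruments(records, GENE, None, None)
        assert len(iv) == 0
        assert iv.provenance["significant"] == 0

    def test_f_exactly_ten_dropped(self):
        # choose beta so F == 10 exactly: pve = 10/(n-2+10)
        n = 1000
        pve = 10 / (n - 2 + 10)
        se = 0.01
        beta = float(np.sqrt(pve * n * se**2 / (1 - pve)))
        rec = make_record(snp="rs_f10", pos=GENE.tss_pos, beta=beta, se=se, pval=1e-10, n=n)
        _, f = snp_strength(rec)
        assert f == pytest.approx(10.0, abs=1e-9)
        iv = build_instruments([rec], GENE, None, None)
        assert len(iv) == 0

    def test_set_filters_commute(self, rng):
        """Significance, MHC, cis and strength are set intersections: order-free."""
        from itertools import permutations

        records = []
        for i in range(40):
            records.append(
                make_record(
                    snp=f"rs{i}",
                    chrom=str(rng.choice(["1", "6"])),
                    pos=int(rng.integers(20_000_000, 60_000_000)),
                    beta=float(rng.normal(0, 0.2)),
                    se=0.01,
                    pval=float(10 ** rng.uniform(-12, -2)),
                    n=10_000,
                )
            )
        gene = GeneAnnotation("G", "P", "1", 40_000_000)
        filters = {
            "sig": lambda rs: filter_significant(rs, 5e-8),
            "mhc": lambda rs: filter_mhc(rs),
            "cis": lambda rs: filter_cis(rs, gene),
            "strength": lambda rs: [r for r in rs if snp_strength(r)[1] > 10],
        }
        results = set()
        for order in permutations(filters):
            kept = records
            for name in order:
                kept = filters[name](kept)
            results.add(tuple(r.snp_id for r in kept))
        assert len(results) == 1


class TestLdMatrixIo:
    def test_round_trip(self, tmp_path):
        ids = ["rs1", "rs2", "rs3"]
        ld = 0.4 ** np.abs(np.subtract.outer(np.arange(3), np.arange(3)))
        path = tmp_path / "r.ld"
        write_ld_matrix(path, ld, ids)
        back, back_ids = read_ld_matrix(path)
        assert back_ids == ids
        np.testing.assert_allclose(back, ld, atol=1e-6)
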