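import hashlib
import math
from pathlib import Path

import numpy as np
import pytest
from scipy import stats

from mirmeth.intervals import gap_distance
from mirmeth.methylome import count_reads_in_windows
from mirmeth.synth import (
    DEMETHYLATED_SAMPLE,
    REFERENCE_SAMPLE,
    WorldConfig,
    amplicon_cpg_positions,
    generate_bisulfite,
    generate_expression,
    generate_mbd_reads,
    generate_qpcr,
    generate_world,
)


def checksums(directory: Path) -> dict[str, str]:
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(directory.iterdir())
    }


class TestWorldGeneration:
    def test_same_seed_gives_identical_files(self, tmp_path):
        cfg = WorldConfig(seed=5)
        generate_world(cfg, out_dir=tmp_path / "a")
        generate_world(cfg, out_dir=tmp_path / "b")
        assert checksums(tmp_path / "a") == checksums(tmp_path / "b")

    def test_different_seeds_differ(self, tmp_path):
        generate_world(WorldConfig(seed=5), out_dir=tmp_path / "a")
        generate_world(WorldConfig(seed=6), out_dir=tmp_path / "b")
        assert checksums(tmp_path / "a") != checksums(tmp_path / "b")

    def test_no_mirnas_degenerate_world(self):
        world = generate_world(WorldConfig(seed=0, n_mirnas=0, n_transcripts=0))
        assert world.mirnas == []
        assert world.manifest.regulated_mirnas == []

    def test_methylated_fraction_and_proximity_invariant(self):
        cfg = WorldConfig(seed=1, n_mirnas=50, frac_methylated_mirnas=0.3,
                          genome_length=210_000)
        world = generate_world(cfg)
        m = world.manifest
        planted = (
            set(m.regulated_mirnas) | set(m.coregulated_mirnas)
            | set(m.imprinted_or_known_ids)
        )
        assert len(planted) == 15
        by_id = {x.mirna_id: x for x in world.mirnas}
        # exhaustive check: every planted id within 500 bp of its region
        for mid, region in m.region_by_mirna.items():
            assert gap_distance(by_id[mid].stemloop, region) <= 500

    def test_regulated_and_coregulated_disjoint(self, zero_noise_world):
        m = zero_noise_world.manifest
        assert not set(m.regulated_mirnas) & set(m.coregulated_mirnas)

    def test_infeasible_placement_reported(self):
        with pytest.raises(ValueError, match="slots"):
            generate_world(WorldConfig(seed=0, n_mirnas=500))

    def test_config_validation(self):
        with pytest.raises(ValueError, match="peak_enrichment"):
            WorldConfig(peak_enrichment=0.5)
        with pytest.raises(ValueError, match="frac_methylated"):
            WorldConfig(frac_methylated_mirnas=1.5)


class TestMBDReads:
    def test_no_background_reads_all_in_planted_regions(self):
        cfg = WorldConfig(seed=2, background_read_rate=0.0)
        world = generate_world(cfg)
        reads = generate_mbd_reads(world.manifest, cfg, REFERENCE_SAMPLE)
        regions = world.manifest.methylated_regions[REFERENCE_SAMPLE]
        for r in reads:
            assert any(reg.contains(r) for reg in regions)

    def test_demethylated_sample_loses_unretained_peaks(self, zero_noise_world):
        m = zero_noise_world.manifest
        demeth = {(r.chrom, r.start) for r in m.methylated_regions[DEMETHYLATED_SAMPLE]}
        for mid in m.lost_mirnas:
            region = m.region_by_mirna[mid]
            assert (region.chrom, region.start) not in demeth
        for mid in m.retained_mirnas:
            region = m.region_by_mirna[mid]
            assert (region.chrom, region.start) in demeth

    def test_background_windows_fit_poisson(self):
        """Chi-square goodness of fit of off-region window counts, ~10k windows."""
        cfg = WorldConfig(seed=3, n_mirnas=4, n_transcripts=2,
                          genome_length=2_500_000, n_chroms=2,
                          n_known_regulated=0, n_imprinted=0, n_coregulated=0)
        world = generate_world(cfg)
        reads = generate_mbd_reads(world.manifest, cfg, REFERENCE_SAMPLE)
        wc = count_reads_in_windows(reads, 500, cfg.chrom_sizes)
        planted = world.manifest.methylated_regions[REFERENCE_SAMPLE]
        counts = np.array(
            [
                c
                for iv, c in wc.counts.items()
                if all(gap_distance(iv, reg) > 500 for reg in planted)
            ]
        )
        assert counts.size > 9000
        lam = counts.mean()
        kmax = int(stats.poisson.ppf(0.999, lam))
        observed = np.bincount(np.minimum(counts, kmax + 1))
        expected = stats.poisson.pmf(np.arange(len(observed) - 1), lam) * counts.size
        expected = np.append(expected, counts.size - expected.sum())
        keep = expected > 5
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        dof = keep.sum() - 2  # one estimated parameter
        p = stats.chi2.sf(chi2, dof)
        assert p > 0.01


class TestExpressionGenerator:
    def test_zero_cv_replicates_identical(self, zero_noise_inputs):
        expr = zero_noise_inputs["expression"]
        spread = expr.groupby(["mirna_id", "cell_line"]).value.agg(lambda v: v.max() - v.min())
        assert (spread == 0).all()

    def test_null_silencing_factor_means_no_differential(self):
        cfg = WorldConfig(seed=4, expression_silencing_factor=1.0, replicate_cv=0.0)
        world = generate_world(cfg)
        expr = generate_expression(world.manifest, cfg)
        folds = expr.pivot_table(index="mirna_id", columns="cell_line", values="value")
        assert np.allclose(folds["DKOlike"], folds["HCT116like"])

    def test_planted_fold_recovered_within_standard_error(self):
        """Monte-Carlo moments: mean ratio ~ 3.0 +/- 3 SE at CV 0.1, n=3."""
        cfg = WorldConfig(seed=5, expression_silencing_factor=3.0, replicate_cv=0.1)
        rng = np.random.default_rng(cfg.seed)
        n_sim = 1000
        sigma = math.sqrt(math.log1p(0.01))
        ratios = []
        for _ in range(n_sim):
            ref = 100 * rng.lognormal(-sigma**2 / 2, sigma, 3)
            dem = 300 * rng.lognormal(-sigma**2 / 2, sigma, 3)
            ratios.append(dem.mean() / ref.mean())
        se = np.std(ratios, ddof=1) / math.sqrt(n_sim)
        assert abs(np.mean(ratios) - 3.0) < 3 * se + 3 * 0.01  # small ratio bias term

    def test_lost_mirnas_upregulated_retained_stay_flat(self, zero_noise_inputs):
        m = zero_noise_inputs["manifest"]
        expr = zero_noise_inputs["expression"]
        means = expr.pivot_table(index="mirna_id", columns="cell_line", values="value")
        fold = means["DKOlike"] / means["HCT116like"]
        for mid in m.lost_mirnas:
            assert fold[mid] == pytest.approx(3.0)
        for mid in m.retained_mirnas:
            assert fold[mid] == pytest.approx(1.0)


class TestBisulfiteGenerator:
    def test_extreme_probabilities_are_deterministic(self):
        cfg = WorldConfig(seed=6, bisulfite_conversion_rate=1.0, cpg_meth_high=1.0)
        world = generate_world(cfg)
        clones = generate_bisulfite(world.manifest, cfg, world.amplicons)
        positions = amplicon_cpg_positions()
        locus = next(iter(clones))
        for seq in clones[locus][REFERENCE_SAMPLE]:
            assert all(seq[p] == "C" for p in positions)

    def test_observed_methylation_within_binomial_interval(self):
        cfg = WorldConfig(seed=7, cpg_meth_high=0.5, bisulfite_conversion_rate=1.0,
                          n_clones=8)
        world = generate_world(cfg)
        clones = generate_bisulfite(world.manifest, cfg, world.amplicons)
        positions = amplicon_cpg_positions()
        locus = next(iter(clones))
        meth = sum(
            seq[p] == "C"
            for seq in clones[locus][REFERENCE_SAMPLE]
            for p in positions
        )
        lo, hi = stats.binom.interval(0.99, 8 * len(positions), 0.5)
        assert lo <= meth <= hi


class TestQPCRGenerator:
    def test_untreated_baseline_normalizes_to_one(self, zero_noise_inputs):
        table = zero_noise_inputs["qpcr"]
        sub = table[table.condition == "untreated"]
        dct = sub.ct_target - sub.ct_reference
        assert np.allclose(dct, dct.iloc[0])

    def test_hosts_of_coregulated_mirnas_respond(self, zero_noise_inputs):
        m = zero_noise_inputs["manifest"]
        table = zero_noise_inputs["qpcr"]
        for mid in m.coregulated_mirnas:
            host = m.host_by_mirna[mid]
            sub = table[table.target == host]
            dct = sub.groupby("condition").apply(
                lambda g: (g.ct_target - g.ct_reference).mean(), include_groups=False
            )
            assert dct["untreated"] - dct["treated"] == pytest.approx(2.0)  # log2(4)
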