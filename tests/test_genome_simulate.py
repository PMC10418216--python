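"""Toy genome construction and the synthetic methylome/readout generators."""

import io

import numpy as np
import pytest

from epicen.config import SimulationConfig, stream
from epicen.genome import build_toy_genome
from epicen.simulate import (
    CHIP_MULTIPLIERS,
    GenotypeSpec,
    hairpin_spec,
    quadruple_mutant,
    simulate_chip_coverage,
    simulate_cytology,
    simulate_line_methylome,
    simulate_methylome,
    simulate_recombinant_lines,
    suppressor_panel,
    triple_mutant,
)


class TestToyGenome:
    def test_deterministic_fasta(self, config):
        buffers = []
        for _ in range(2):
            g = build_toy_genome(config)
            buf = io.StringIO()
            g.write_fasta(buf)
            buffers.append(buf.getvalue())
        assert buffers[0] == buffers[1]

    def test_element_counts_and_containment(self, genome):
        a5 = genome.elements("ATHILA5", genome.focal_chrom)
        assert len(a5) == 3
        hp = genome.hairpin_span
        src = genome.hairpin_source
        assert src.start <= hp.start < hp.end <= src.end
        for a in genome.annotations:
            assert 0 <= a.start < a.end <= genome.length(a.chrom)

    def test_satellites_tile_centromere_outside_elements(self, genome):
        chrom = genome.focal_chrom
        cs, ce = genome.centromeres[chrom]
        roles = genome.role_array(chrom)[cs:ce]
        assert set(np.unique(roles)) <= {"satellite_array", "ATHILA5",
                                         "ATHILA_other"}

    def test_oversized_element_rejected(self, config):
        with pytest.raises(ValueError, match="centromere"):
            build_toy_genome(config, athila5_length=30_000)

    def test_short_chromosome_rejected(self):
        cfg = SimulationConfig(seed=1, chrom_length=5_000)
        with pytest.raises(ValueError, match="10 kb"):
            build_toy_genome(cfg)


class TestMethylome:
    def test_all_zero_targets_give_zero_counts(self, genome, config):
        zero = GenotypeSpec("null", {r: {c: 0.0 for c in ("CG", "CHG", "CHH")}
                                     for r in ("satellite_array", "ATHILA5",
                                               "ATHILA_other", "gene",
                                               "intergenic")})
        calls = simulate_methylome(genome, zero, config)
        assert (calls["n_meth"] == 0).all()

    def test_counts_conserved_and_positions_are_cytosines(self, genome,
                                                          config):
        calls = simulate_methylome(genome, triple_mutant(), config)
        assert (calls["n_meth"] <= calls["n_total"]).all()
        assert (calls["n_total"] > 0).all()
        sub = calls[calls["chrom"] == genome.focal_chrom].head(500)
        seq = genome.sequence(genome.focal_chrom)
        for r in sub.itertuples():
            assert seq[r.pos] == ("C" if r.strand == "+" else "G")

    def test_ddm1_satellites_lose_cg_but_keep_chh(self, genome, config):
        calls = simulate_methylome(genome, quadruple_mutant(), config)
        chrom = genome.focal_chrom
        roles = genome.role_array(chrom)
        sat = calls[calls["chrom"] == chrom]
        sat = sat[roles[sat["pos"].to_numpy()] == "satellite_array"]
        lv = {c: sat[sat["context"] == c]["n_meth"].sum()
              / sat[sat["context"] == c]["n_total"].sum()
              for c in ("CG", "CHH")}
        assert lv["CG"] < lv["CHH"]

    def test_hairpin_restores_chg_chh_not_cg_in_trans(self, genome, config):
        from epicen.simulate import _hairpin_target_spans

        base = simulate_methylome(genome, quadruple_mutant(), config)
        hp = simulate_methylome(genome, hairpin_spec(), config)
        spans = [s for s in _hairpin_target_spans(genome)
                 if not (s[1] <= genome.hairpin_span.start < s[2])]
        assert spans  # non-source ATHILA5 copies carry homologous spans

        def span_level(calls, ctx):
            sel = []
            for chrom, s, e in spans:
                sub = calls[(calls["chrom"] == chrom) & (calls["pos"] >= s)
                            & (calls["pos"] < e)
                            & (calls["context"] == ctx)]
                sel.append(sub)
            import pandas as pd
            cat = pd.concat(sel)
            return cat["n_meth"].sum() / cat["n_total"].sum()

        spec = hairpin_spec()
        for ctx in ("CHG", "CHH"):
            gain = span_level(hp, ctx) - span_level(base, ctx)
            expected = (spec.hairpin_levels[ctx]
                        - quadruple_mutant().level("ATHILA5", ctx))
            assert gain == pytest.approx(expected, abs=0.05)
        assert abs(span_level(hp, "CG") - span_level(base, "CG")) < 0.03

    def test_unknown_role_is_reported(self, genome, config):
        spec = GenotypeSpec("partial", {"gene": {"CG": 0.1, "CHG": 0.1,
                                                 "CHH": 0.1}})
        with pytest.raises(ValueError, match="no target level for role"):
            simulate_methylome(genome, spec, config)

    def test_empirical_means_converge_to_targets(self, genome):
        cfg = SimulationConfig(seed=9, coverage_mean=200.0)
        spec = triple_mutant()
        calls = simulate_methylome(genome, spec, cfg)
        chrom = genome.focal_chrom
        roles = genome.role_array(chrom)
        sub = calls[calls["chrom"] == chrom]
        for role in ("satellite_array", "gene"):
            m = sub[roles[sub["pos"].to_numpy()] == role]
            for ctx in ("CG", "CHG", "CHH"):
                mm = m[m["context"] == ctx]
                level = mm["n_meth"].sum() / mm["n_total"].sum()
                assert level == pytest.approx(spec.level(role, ctx),
                                              abs=0.02)

    def test_determinism_for_fixed_config(self, genome, config):
        a = simulate_methylome(genome, triple_mutant(), config)
        b = simulate_methylome(genome, triple_mutant(), config)
        assert a.equals(b)


class TestRecombinantLines:
    def test_no_crossover_limit(self, genome):
        cfg = SimulationConfig(seed=3, crossover_rate_arm=1e-12,
                               crossover_rate_centromere=1e-13)
        lines = simulate_recombinant_lines(genome, cfg, n_lines=30)
        for line in lines:
            for chrom in genome.chrom_names:
                assert len(line.blocks[chrom]) == 1
            origin = line.blocks[genome.focal_chrom][0][2]
            assert (line.phenotype == "sterile") == (origin == "ddm1_derived")

    def test_phenotype_rule_matches_causative_coverage(self, genome, config):
        # dominant epiallele: sterile iff the causative interval is entirely
        # ddm1-derived
        src = genome.hairpin_source
        lines = simulate_recombinant_lines(genome, config, n_lines=60)
        for line in lines:
            assert (line.phenotype == "sterile") == covered_all(line, src)

    def test_transmission_probability_matches_gamete_enumeration(self, genome):
        # with a point-like causative locus, enumerating the two gamete
        # classes of the heterozygous F1 gives P(sterile) = 1/2
        cfg = SimulationConfig(seed=5)
        lines = simulate_recombinant_lines(genome, cfg, n_lines=400)
        frac = np.mean([l.phenotype == "sterile" for l in lines])
        assert frac == pytest.approx(0.5, abs=3 * np.sqrt(0.25 / 400))

    def test_crossover_rates_match_poisson_means(self, genome):
        cfg = SimulationConfig(seed=6, crossover_rate_arm=1.0,
                               crossover_rate_centromere=0.1)
        lines = simulate_recombinant_lines(genome, cfg, n_lines=300)
        chrom = genome.focal_chrom
        cs, ce = genome.centromeres[chrom]
        n_arm = n_cen = 0
        for line in lines:
            for x in line.crossovers[chrom]:
                if cs <= x < ce:
                    n_cen += 1
                else:
                    n_arm += 1
        assert n_arm / 300 == pytest.approx(1.0, abs=3 * np.sqrt(1.0 / 300))
        assert n_cen / 300 == pytest.approx(0.1, abs=3 * np.sqrt(0.1 / 300))

    def test_zero_lines_rejected(self, genome, config):
        with pytest.raises(ValueError):
            simulate_recombinant_lines(genome, config, n_lines=0)

    def test_line_methylome_follows_block_origin(self, genome, config):
        cfg = SimulationConfig(seed=8, crossover_rate_arm=1e-12,
                               crossover_rate_centromere=1e-13)
        lines = simulate_recombinant_lines(genome, cfg, n_lines=6)
        sterile = next(l for l in lines if l.phenotype == "sterile")
        calls = simulate_line_methylome(genome, sterile, config)
        chrom = genome.focal_chrom
        cs, ce = genome.centromeres[chrom]
        sat = calls[(calls["chrom"] == chrom) & (calls["context"] == "CG")
                    & (calls["pos"] >= cs) & (calls["pos"] < ce)]
        level = sat["n_meth"].sum() / sat["n_total"].sum()
        assert level < 0.15  # whole chromosome ddm1-derived: CG lost


class TestChipCoverage:
    def test_null_multiplier_gives_flat_enrichment(self, genome, config):
        from epicen.metaplot import chip_enrichment, element_group, \
            metaprofile_track

        flat = {r: 1.0 for r in CHIP_MULTIPLIERS["wt"]}
        ip, inp = simulate_chip_coverage(genome, flat, config)
        enr = chip_enrichment(ip, inp)
        prof = metaprofile_track(enr, element_group(genome, "ATHILA_other"))
        assert np.nanmax(np.abs(prof["mean"])) < 0.3

    def test_gapless_cover(self, genome, config):
        ip, _ = simulate_chip_coverage(genome, CHIP_MULTIPLIERS["wt"], config)
        for chrom in genome.chrom_names:
            sub = ip[ip["chrom"] == chrom].sort_values("start")
            assert sub["start"].iloc[0] == 0
            assert sub["end"].iloc[-1] == genome.length(chrom)
            assert (sub["start"].to_numpy()[1:]
                    == sub["end"].to_numpy()[:-1]).all()

    def test_negative_multiplier_rejected(self, genome, config):
        with pytest.raises(ValueError):
            simulate_chip_coverage(genome, {"satellite_array": -1.0}, config)


class TestCytologySimulation:
    def test_zero_rate_means_all_normal(self, config):
        recs = simulate_cytology(config, rates={"WT": 0.0})
        ana = [r for r in recs if r.stage == "anaphase"]
        assert len(ana) == config.n_cells_scored
        assert all(r.n_lagging == 0 for r in ana)

    def test_full_bias_attributes_every_event_to_focal(self, config):
        recs = simulate_cytology(config, rates={"m": 0.31}, chr5_bias=1.0)
        fish = [r for r in recs if r.fish_probe_chromosome == "Chr5"]
        assert fish and all(r.fish_colocalized for r in fish)

    def test_bias_out_of_range_rejected(self, config):
        with pytest.raises(ValueError):
            simulate_cytology(config, rates={"m": 0.1}, chr5_bias=1.5)


class TestSuppressorPanel:
    def test_shared_locus_on_dmr_grid_at_hairpin_source(self, genome, config):
        specs, shared = suppressor_panel(genome, config)
        assert len(specs) == 4
        chrom, start, end = shared
        assert chrom == genome.focal_chrom and start % 300 == 0
        src = genome.hairpin_source
        assert start <= src.start < end  # covers the element's 5' region
        for spec in specs:
            assert shared in spec.hyper_loci
            assert len(spec.hyper_loci) == 6  # shared + 5 private


def covered_all(line, src):
    covered = sum(min(e, src.end) - max(s, src.start)
                  for s, e in line.spans(src.chrom, "ddm1_derived")
                  if min(e, src.end) > max(s, src.start))
    return covered == src.end - src.start


def test_invalid_genotype_levels_rejected():
    with pytest.raises(ValueError):
        GenotypeSpec("bad", {"gene": {"CG": 1.5, "CHG": 0, "CHH": 0}})
    with pytest.raises(ValueError, match="CG"):
        GenotypeSpec("bad", {"gene": {"CG": 0.1, "CHG": 0.1, "CHH": 0.1}},
                     hairpin_levels={"CG": 0.5})


def test_config_invariants():
    with pytest.raises(ValueError):
        SimulationConfig(seed=1, crossover_rate_arm=0.1,
                         crossover_rate_centromere=0.2)
    with pytest.raises(ValueError):
        SimulationConfig(seed=1, n_cells_scored=0)


def test_rng_streams_are_independent_and_reproducible():
    a = stream(11, "x").normal(size=3)
    b = stream(11, "x").normal(size=3)
    c = stream(11, "y").normal(size=3)
    np.testing.assert_array_equal(a, b)
    assert not np.allclose(a, c)
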