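"""Generator contracts: reference geometry, Ψ truth, assay mechanisms."""

import numpy as np
import pandas as pd
import pytest

from psiseq import simdata as sd


class TestBuildReference:
    def test_composition_minimums(self, reference, small_config):
        ref, truth = reference
        cfg = small_config
        trnas = ref.features("tRNA")
        assert len(trnas) >= 8
        assert len(ref.features("miRNA_mature")) >= 20
        assert len({f.family for f in ref.features("TE")}) >= 5
        assert len(ref.features("piRNA_cluster")) >= 2
        rrna_sites = [t for t in truth if t.ref == "rRNA" and t.enzyme == "DKC1"]
        assert len(rrna_sites) == cfg.n_rrna_psi

    def test_trna_geometry_and_psi55(self, reference):
        ref, truth = reference
        pus10 = {(t.ref, t.pos) for t in truth if t.enzyme == "PUS10"}
        for f in ref.features("tRNA"):
            seq = ref.sequences[f.ref]
            assert len(seq) == 76
            assert seq.endswith("CCA")
            assert seq[54] == "T"
            # position 55 (0-based 54) is the canonical PUS10 target
            assert (f.ref, 54) in pus10

    def test_psi_sites_sit_on_uridine(self, reference):
        ref, truth = reference
        for t in truth:
            assert ref.sequences[t.ref][t.pos] == "T"

    def test_unuar_motif_definition(self):
        # U-N-U-A-R with N=A, R=G: the modified U is the third base
        assert sd.find_unuar("TATAG") == [2]
        assert sd.find_unuar("TATAC") == []  # R must be a purine

    def test_pus7_sites_sit_in_unuar_motifs(self, reference):
        ref, truth = reference
        for t in truth:
            if t.enzyme == "PUS7":
                assert t.pos in sd.find_unuar(ref.sequences[t.ref])

    @pytest.mark.parametrize("genotype,enzyme", [
        ("pus7", "PUS7"), ("pus10", "PUS10"), ("dkc1", "DKC1")])
    def test_genotype_knockout_removes_enzyme_class(self, genotype, enzyme):
        cfg = sd.SimConfig(seed=42, depth=1000, genotype=genotype)
        _, truth = sd.build_reference(cfg)
        assert all(t.enzyme != enzyme for t in truth)
        assert truth  # other classes remain

    def test_invalid_size_range_rejected(self):
        cfg = sd.SimConfig(seed=0, size_ranges={"miRNA": (22, 20)})
        with pytest.raises(sd.ConfigError):
            cfg.validate()


class TestPool:
    def test_deterministic_under_fixed_seed(self, small_config, reference):
        ref, truth = reference
        a = sd.simulate_pool(ref, truth, small_config)
        b = sd.simulate_pool(ref, truth, small_config)
        pd.testing.assert_frame_equal(a, b)

    def test_3p_trfs_are_cca_suffixes(self, pool, reference):
        ref, _ = reference
        trf = pool[pool["cls"] == "tRF_3p"]
        assert len(trf) > 0
        for row in trf.itertuples():
            parent = ref.sequences[row.ref]
            assert parent.endswith(row.sequence)
            assert row.sequence.endswith("CCA")

    def test_abundance_sums_to_depth(self, pool, small_config):
        assert pool["true_abundance"].sum() == pytest.approx(small_config.depth)

    def test_class_length_windows(self, pool):
        for cls, (lo, hi) in [("miRNA", (20, 22)), ("tRF_3p", (18, 30)),
                              ("piRNA", (26, 31))]:
            lens = pool.loc[pool["cls"] == cls, "sequence"].str.len()
            assert lens.between(lo, hi).all()


class TestIP:
    def test_bound_plus_unbound_conserves_pool_draw(self, pool, small_config, tmp_path):
        out = sd.simulate_ip(pool, small_config, tmp_path)
        assert (out.counts["bound"] + out.counts["unbound"]).sum() == small_config.depth

    def test_degenerate_capture_splits_by_psi(self, pool, tmp_path):
        cfg = sd.SimConfig(seed=42, depth=5000, ip_capture=(0.0, 1.0))
        out = sd.simulate_ip(pool, cfg, tmp_path)
        merged = out.counts.merge(pool[["species", "n_psi"]], on="species")
        psi = merged["n_psi"] > 0
        assert merged.loc[psi, "unbound"].sum() == 0
        assert merged.loc[~psi, "bound"].sum() == 0

    def test_capture_rate_matches_binomial_oracle(self, reference, tmp_path):
        # eps_psi=0.8 at depth 1e5: observed bound fraction of Ψ species
        # within 3 SE of the binomial expectation
        ref, truth = reference
        cfg = sd.SimConfig(seed=7, depth=100_000, ip_capture=(0.05, 0.8))
        pool = sd.simulate_pool(ref, truth, cfg)
        out = sd.simulate_ip(pool, cfg, tmp_path)
        merged = out.counts.merge(pool[["species", "n_psi"]], on="species")
        psi = merged[merged["n_psi"] > 0]
        n = (psi["bound"] + psi["unbound"]).sum()
        frac = psi["bound"].sum() / n
        se = np.sqrt(0.8 * 0.2 / n)
        assert abs(frac - 0.8) <= 3 * se

    def test_inverted_capture_warns(self, pool, tmp_path):
        cfg = sd.SimConfig(seed=1, depth=1000, ip_capture=(0.8, 0.05))
        with pytest.warns(UserWarning, match="inverts"):
            sd.simulate_ip(pool, cfg, tmp_path)


class TestCMC:
    def test_full_block_removes_psi_species(self, pool, tmp_path):
        cfg = sd.SimConfig(seed=42, depth=5000, cmc_alpha=1.0, log_events=True)
        out = sd.simulate_cmc(pool, cfg, tmp_path, mode="stop")
        merged = out.counts.merge(pool[["species", "n_psi"]], on="species")
        assert merged.loc[merged["n_psi"] > 0, "treated"].sum() == 0
        # and the event log accounts for every dropped read
        dropped = out.events[out.events["events"] == "rt_stop"]
        assert len(dropped) > 0

    @staticmethod
    def _one_species_pool(seq: str, psi_offsets: str, depth: int) -> pd.DataFrame:
        return pd.DataFrame([dict(
            species="sp0", sequence=seq, ref="locus", start=0, end=len(seq),
            cls="tile", family="", psi_offsets=psi_offsets,
            n_psi=len(psi_offsets.split(",")) if psi_offsets else 0,
            true_abundance=float(depth))])

    def test_multi_site_dropout_probability(self, tmp_path):
        # alpha=0.9, 2 Ψ sites: per-read survival (1-0.9)^2 = 0.01
        n = 100_000
        pool = self._one_species_pool("ACGTTACGTACGTTACGTACGT", "3, 12".replace(" ", ""), n)
        cfg = sd.SimConfig(seed=9, depth=n, cmc_alpha=0.9, base_error=0.0)
        out = sd.simulate_cmc(pool, cfg, tmp_path, mode="stop")
        survived = int(out.counts["treated"].iloc[0])
        se = np.sqrt(n * 0.01 * 0.99)
        assert abs(survived - 0.01 * n) <= 3 * se

    def test_mn_rates_match_binomial_oracle(self, tmp_path):
        # m=0.3, d=0.1 over 1e4 reads spanning one Ψ site
        n = 10_000
        pool = self._one_species_pool("ACGTTACGTACGATCGATCGAT", "3", n)
        cfg = sd.SimConfig(seed=0, depth=n, mn_rates=(0.3, 0.1),
                           base_error=0.0, log_events=True)
        out = sd.simulate_cmc(pool, cfg, tmp_path, mode="mn2plus")
        ev = out.events[out.events["read"].str.contains("treated")]
        assert len(ev) == n
        mm_frac = ev["events"].str.startswith("mm@").mean()
        del_frac = ev["events"].str.startswith("del@").mean()
        assert abs(mm_frac - 0.3) <= 4 * np.sqrt(0.3 * 0.7 / n)
        assert abs(del_frac - 0.1) <= 4 * np.sqrt(0.1 * 0.9 / n)

    def test_pus10_knockout_has_no_position55_events(self, tmp_path):
        cfg = sd.SimConfig(seed=13, depth=20_000, genotype="pus10",
                           base_error=0.0, log_events=True)
        ref, truth = sd.build_reference(cfg)
        pool = sd.simulate_pool(ref, truth, cfg)
        out = sd.simulate_cmc(pool, cfg, tmp_path, mode="mn2plus")
        trf = pool[pool["cls"] == "tRF_3p"].set_index("species")
        ev = out.events[out.events["events"] != "."]
        for row in ev.itertuples():
            if row.species in trf.index:
                start = trf.loc[row.species, "start"]
                for e in row.events.split(";"):
                    off = int(e.split("@")[1].split(">")[0])
                    assert start + off != 54, "Ψ-55 event in pus10 knockout"


def test_fastq_byte_determinism(pool, small_config, tmp_path):
    a = sd.simulate_ip(pool, small_config, tmp_path / "a")
    b = sd.simulate_ip(pool, small_config, tmp_path / "b")
    for key in a.fastq:
        assert a.fastq[key].read_bytes() == b.fastq[key].read_bytes()
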