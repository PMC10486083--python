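"""The generator's own contracts: determinism, planted-truth exactness,
calibrated randomness."""

import numpy as np
import pytest

from retromir.core import splice
from retromir.simulate import (
    SimConfig,
    SimulationError,
    evolve_cds,
    retrocopy_sequence,
    simulate_all,
    simulate_codon_pair,
    simulate_genome,
    simulate_ortholog,
    write_outputs,
)
from retromir.structure import assess_hairpin


class TestDeterminism:
    def test_genome_byte_identical(self, tmp_path):
        cfg = SimConfig(n_genes=5, n_retrocopies=3, plant_r=1, plant_ej=1, plant_n=1)
        a = simulate_all(cfg)
        b = simulate_all(cfg)
        assert a.genome.sequences == b.genome.sequences
        write_outputs(a, tmp_path / "a")
        write_outputs(b, tmp_path / "b")
        for f in sorted((tmp_path / "a").rglob("*")):
            if f.is_file():
                other = tmp_path / "b" / f.relative_to(tmp_path / "a")
                assert f.read_bytes() == other.read_bytes(), f.name

    def test_seed_changes_output(self):
        a = simulate_all(SimConfig(n_genes=5, n_retrocopies=3, plant_r=1, plant_ej=1, plant_n=1))
        b = simulate_all(SimConfig(seed=2, n_genes=5, n_retrocopies=3, plant_r=1, plant_ej=1, plant_n=1))
        assert a.genome.sequences != b.genome.sequences


class TestGenome:
    def test_gene_count_and_planted_hairpins(self, sim_default):
        cfg = sim_default.config
        assert len(sim_default.transcripts) == cfg.n_genes
        # every planted retro-miR precursor passes the assessor
        retro_by_id = {r.id: r for r in sim_default.retrocopies}
        for row in sim_default.truth.retromirs:
            if row["true_class"] == "repeat":
                continue
            rc = retro_by_id[row["retrocopy_id"]]
            a, b = row["precursor_retro_span"]
            assert assess_hairpin(rc.sequence[a:b])[0], row["id"]

    def test_infeasible_hairpin_errors(self):
        with pytest.raises(SimulationError):
            SimConfig(utr3_len=50).validate()  # hairpin longer than the UTR

    def test_no_room_for_insertion_errors(self):
        cfg = SimConfig(n_genes=4, n_retrocopies=3, plant_r=1, plant_ej=1,
                        plant_n=1, max_retro_chrom=800)
        with pytest.raises(SimulationError, match="intergenic"):
            simulate_all(cfg)


class TestRetrotransposition:
    def test_zero_rates_give_exact_copy(self, sim_default):
        # default config: mutation rate 0, truncation 0 => R/EJ retrocopies
        # equal their spliced parent mRNA exactly
        for rc in sim_default.retrocopies:
            tx = sim_default.transcripts[rc.parental_transcript_id]
            mrna = splice(sim_default.genome, tx)
            row = next(r for r in sim_default.truth.retromirs
                       if r.get("retrocopy_id") == rc.id and r["true_class"] in ("R", "EJ"))\
                if any(r.get("retrocopy_id") == rc.id and r["true_class"] in ("R", "EJ")
                       for r in sim_default.truth.retromirs) else None
            if row is not None:
                assert rc.sequence == mrna

    def test_mutation_count_binomial(self, rng):
        L, rate, reps = 10000, 0.01, 200
        mrna = "".join(rng.choice(list("ACGT"), L))
        counts = [len(retrocopy_sequence(mrna, rate, 0.0, rng)[1]) for _ in range(reps)]
        mean = np.mean(counts)
        se = np.sqrt(L * rate * (1 - rate) / reps)
        assert abs(mean - L * rate) < 3 * se

    def test_r_plant_overlaps_parental_mature_fully(self, sim_default):
        # by construction, the R retro-miR precursor copies the parental one
        for row in sim_default.truth.retromirs:
            if row["true_class"] != "R":
                continue
            a, b = row["mature_retro_span"]
            assert b - a == sim_default.config.mature_len


class TestOrthologs:
    def test_zero_divergence_identity(self, rng):
        s = "".join(rng.choice(list("ACGT"), 500))
        assert simulate_ortholog(s, 0.0, rng) == s

    def test_full_divergence_no_matches(self, rng):
        s = "".join(rng.choice(list("ACGT"), 500))
        o = simulate_ortholog(s, 1.0, rng)
        assert sum(a == b for a, b in zip(s, o)) == 0

    def test_divergence_binomial(self, rng):
        L, d, reps = 1000, 0.1, 50
        s = "".join(rng.choice(list("ACGT"), L))
        idents = [sum(a == b for a, b in zip(s, simulate_ortholog(s, d, rng))) / L
                  for _ in range(reps)]
        se = np.sqrt(d * (1 - d) / L / reps)
        assert abs(np.mean(idents) - (1 - d)) < 3 * se


class TestCodonEvolution:
    def test_zero_steps_identical(self, rng):
        c1, c2 = simulate_codon_pair(50, 1.0, 0, rng)
        assert c1 == c2

    def test_omega_zero_only_synonymous(self, rng):
        from retromir.selection import dnds_ng86

        c1, c2 = simulate_codon_pair(100, 0.0, 200, rng)
        pairs = [(c1[i:i + 3], c2[i:i + 3]) for i in range(0, len(c1), 3)]
        res = dnds_ng86(pairs)
        assert res.dN == 0.0 and res.dS > 0

    def test_no_stops_created(self, rng):
        from retromir.selection import _STOPS

        _, c2 = simulate_codon_pair(100, 1.0, 500, rng)
        assert not any(c2[i:i + 3] in _STOPS for i in range(0, len(c2), 3))


class TestPlantedSites:
    def test_site_counts_match_ledger_exactly(self, sim_default):
        from retromir.targets import scan_sites

        truth_sites = sim_default.truth.utr_sites
        matures = {m[0]: m[2] for r in sim_default.retro_mirnas for m in r.matures}
        found = []
        for mid, seq in matures.items():
            found.extend(scan_sites(mid, seq, sim_default.utrs))
        assert len(found) == len(truth_sites)
        truth_keys = {(t["utr_id"], t["mirna_id"], t["site_type"], t["position"])
                      for t in truth_sites}
        found_keys = {(s.utr_id, s.mirna_id, s.site_type, s.position) for s in found}
        assert found_keys == truth_keys


class TestTruthLedgerCompleteness:
    def test_every_plant_has_one_row(self, sim_default):
        cfg = sim_default.config
        rows = [r for r in sim_default.truth.retromirs if r["true_class"] != "repeat"]
        assert len(rows) == cfg.plant_r + cfg.plant_ej + cfg.plant_n
        assert len({r["id"] for r in rows}) == len(rows)
        assert len(sim_default.truth.retrocopies) == cfg.n_retrocopies
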