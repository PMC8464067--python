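"""Generator contracts: determinism, geometry, planted truth, count models."""

import re

import numpy as np
import pandas as pd
import pytest

from exoregulon import synth
from exoregulon.synth import (
    ExpressionModel,
    GenomeSpec,
    ReadModel,
    generate_reference,
    plant_sites,
    simulate_exo_coverage,
    simulate_occupancy,
    simulate_rnaseq,
)


class TestGenerateReference:
    def test_empty_annotation(self):
        genome, genes = generate_reference(GenomeSpec(length=1000, n_genes=0), seed=0)
        assert len(genome) == 1000
        assert genes.empty

    def test_deterministic(self):
        spec = GenomeSpec(length=20_000, n_genes=15)
        g1, a1 = generate_reference(spec, seed=42)
        g2, a2 = generate_reference(spec, seed=42)
        assert g1 == g2
        pd.testing.assert_frame_equal(a1, a2)

    def test_no_overlaps_and_min_gaps(self):
        # independent oracle: pairwise interval-overlap scan
        spec = GenomeSpec(length=50_000, n_genes=20, min_intergenic=50)
        _, genes = generate_reference(spec, seed=3)
        ivs = sorted(zip(genes["start"], genes["end"]))
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 <= s2, "genes overlap"
            assert s2 - e1 >= 50, "intergenic gap too small"
        assert ivs[0][0] >= 50 and ivs[-1][1] <= 50_000 - 50

    def test_unsatisfiable_spec_raises(self):
        with pytest.raises(ValueError, match="unsatisfiable"):
            generate_reference(GenomeSpec(length=1000, n_genes=10), seed=0)

    def test_operon_members_share_strand(self):
        _, genes = generate_reference(GenomeSpec(length=100_000, n_genes=60), seed=7)
        for _, grp in genes.groupby("operon_id"):
            assert grp["strand"].nunique() == 1


class TestPlantSites:
    def test_regulatory_intragenic_split(self):
        # the YidZ-scale layout: 118 sites, 23% regulatory
        genome, genes = generate_reference(GenomeSpec(length=800_000, n_genes=600), seed=1)
        _, sites = plant_sites(genes, genome, 118, 0.23, seed=1)
        n_reg = (sites["location_class_truth"] == "regulatory").sum()
        assert n_reg == 27
        assert (sites["location_class_truth"] == "intragenic").sum() == 91

    def test_no_sites_leaves_genome_unchanged(self):
        genome, genes = generate_reference(GenomeSpec(length=20_000, n_genes=10), seed=0)
        genome2, sites = plant_sites(genes, genome, 0, 0.5, seed=0)
        assert genome2 == genome
        assert sites.empty

    def test_motif_instances_match_iupac_consensus(self):
        # oracle: regex scan of the output genome
        genome, genes = generate_reference(GenomeSpec(length=100_000, n_genes=60), seed=2)
        genome2, sites = plant_sites(genes, genome, 12, 0.5, motif="TTCNNNNNNGAA", seed=2)
        pattern = re.compile("TTC[ACGT]{6}GAA")
        half = len("TTCNNNNNNGAA") // 2
        for _, s in sites.iterrows():
            start = s.center - half
            written = genome2[start:start + 12]
            assert written == s.motif_instance
            assert pattern.fullmatch(written)

    def test_location_truth_consistent_with_annotation(self):
        genome, genes = generate_reference(GenomeSpec(length=100_000, n_genes=60), seed=2)
        _, sites = plant_sites(genes, genome, 12, 0.5, seed=2)
        for _, s in sites.iterrows():
            inside = ((genes["start"] <= s.center) & (s.center < genes["end"])).any()
            assert inside == (s.location_class_truth == "intragenic")


class TestExoCoverage:
    def test_zero_rates_give_zero_tracks(self):
        sites = pd.DataFrame({"center": [100, 500]})
        model = ReadModel(reads_per_site=0, background_rate=0, mock_fragments=0)
        tracks = simulate_exo_coverage(sites, model, 1000, n_replicates=1, seed=0)
        for pair in tracks.values():
            for t in pair.values():
                assert t.values.sum() == 0

    def test_per_site_read_count_poisson_bound(self):
        # oracle: Poisson tail bound — site sum within 3*sqrt(lambda) of lambda
        # for >= 95% of sites (checked over several seeds)
        centers = np.arange(500, 50_000, 990)[:50]
        sites = pd.DataFrame({"center": centers})
        model = ReadModel(reads_per_site=200, background_rate=0, border_jitter_sd=3)
        ok = total = 0
        for seed in range(3):
            tracks = simulate_exo_coverage(sites, model, 50_000, n_replicates=1, seed=seed)
            fwd = tracks["ip1"]["+"].values
            for c in centers:
                got = fwd[c - 40:c].sum()
                ok += abs(got - 200) <= 3 * np.sqrt(200)
                total += 1
        assert ok / total >= 0.95

    def test_count_conservation_and_determinism(self):
        sites = pd.DataFrame({"center": [1000, 3000]})
        model = ReadModel(background_rate=0.01, mock_fragments=100)
        t1 = simulate_exo_coverage(sites, model, 10_000, n_replicates=2, seed=5)
        t2 = simulate_exo_coverage(sites, model, 10_000, n_replicates=2, seed=5)
        for sample in t1:
            for strand in "+-":
                v1, v2 = t1[sample][strand].values, t2[sample][strand].values
                np.testing.assert_array_equal(v1, v2)
                assert v1.sum() == v1.sum()  # finite
                assert (v1 >= 0).all() and np.allclose(v1, np.round(v1))

    def test_borders_flank_center_symmetrically(self):
        # truth geometry: fwd border at center-offset, rev at center+offset
        sites = pd.DataFrame({"center": [5000]})
        model = ReadModel(reads_per_site=500, background_rate=0, border_jitter_sd=0.0)
        tracks = simulate_exo_coverage(sites, model, 10_000, n_replicates=1, seed=1)
        fwd_peak = int(tracks["ip1"]["+"].values.argmax())
        rev_peak = int(tracks["ip1"]["-"].values.argmax())
        assert fwd_peak == 5000 - model.border_offset
        assert rev_peak == 5000 + model.border_offset
        assert rev_peak - fwd_peak == 2 * model.border_offset

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            simulate_exo_coverage(
                pd.DataFrame({"center": []}),
                ReadModel(mock_fragment_min=500, mock_fragment_max=300),
                1000,
            )


class TestOccupancy:
    def test_all_rnap_rpod(self, toy_genes):
        rnap, rpod, truth = simulate_occupancy(
            toy_genes, {"rnap_rpod": 1.0, "rnap_only": 0.0, "none": 0.0}, seed=0
        )
        assert len(rnap) == len(truth) and len(rpod) == len(truth)
        assert (truth["cooccupancy_truth"] == "rnap_rpod").all()

    def test_rpod_never_without_rnap(self):
        _, genes = generate_reference(GenomeSpec(length=300_000, n_genes=200), seed=4)
        rnap, rpod, _ = simulate_occupancy(
            genes, {"rnap_rpod": 0.4, "rnap_only": 0.3, "none": 0.3}, seed=4
        )
        assert set(rpod) <= set(rnap)

    def test_class_counts_within_binomial_envelope(self):
        from scipy import stats

        _, genes = generate_reference(GenomeSpec(length=400_000, n_genes=260), seed=9)
        fractions = {"rnap_rpod": 0.5, "rnap_only": 0.25, "none": 0.25}
        _, _, truth = simulate_occupancy(genes, fractions, seed=9)
        n = len(truth)
        for cls, p in fractions.items():
            k = (truth["cooccupancy_truth"] == cls).sum()
            lo, hi = stats.binom.ppf([0.005, 0.995], n, p)
            assert lo <= k <= hi

    def test_bad_fractions_rejected(self, toy_genes):
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_occupancy(toy_genes, {"rnap_rpod": 0.5, "rnap_only": 0.2, "none": 0.2})


class TestRnaseq:
    def test_null_has_no_fold_change(self):
        genes = pd.DataFrame({"gene_id": [f"g{i}" for i in range(400)],
                              "strand": "+", "start": 0, "end": 10})
        model = ExpressionModel(baseline_mean=300, dispersion=0.02, n_replicates=4,
                                planted_lfc=0)
        counts = simulate_rnaseq(genes, {}, model, seed=0)
        wt = counts.filter(like="WT").mean(axis=1)
        ko = counts.filter(like="KO").mean(axis=1)
        assert abs(np.log2(ko.mean() / wt.mean())) < 0.05

    def test_planted_shift_direction(self, toy_genes):
        model = ExpressionModel(baseline_mean=500, dispersion=0.01, n_replicates=5)
        counts = simulate_rnaseq(toy_genes, {"gA": "up", "gB": "down"}, model, seed=1)
        lfc = np.log2(counts.filter(like="KO").mean(axis=1) / counts.filter(like="WT").mean(axis=1))
        assert lfc["gA"] > 1.5 and lfc["gB"] < -1.5
        assert abs(lfc.drop(["gA", "gB"])).max() < 0.5

    def test_zero_dispersion_is_poisson(self):
        # oracle: sample variance/mean ratio over 1e4 draws within 5%
        genes = pd.DataFrame({"gene_id": [f"g{i}" for i in range(2500)],
                              "strand": "+", "start": 0, "end": 10})
        model = ExpressionModel(baseline_mean=200, dispersion=0.0, n_replicates=4)
        counts = simulate_rnaseq(genes, {}, model, seed=2)
        draws = counts.to_numpy().ravel()
        assert abs(draws.var() / draws.mean() - 1) < 0.05

    def test_unknown_gene_rejected(self, toy_genes):
        with pytest.raises(ValueError, match="unknown gene"):
            simulate_rnaseq(toy_genes, {"nope": "up"}, ExpressionModel(), seed=0)


def test_truth_tables_complete(small_dataset):
    ds = small_dataset
    assert ds.sites["site_id"].is_unique
    assert len(ds.sites) == 20
    assert set(ds.direct_targets) <= set(ds.sites["target_gene_truth"])
    # every operon-lead promoter labelled exactly once
    assert ds.occupancy_truth["gene_id"].is_unique
    # planted direct targets carry a regulatory mode on their sites
    modes = ds.sites.set_index("target_gene_truth")["regulatory_mode_truth"]
    for g, d in ds.direct_targets.items():
        expected = "repressor" if d == "up" else "activator"
        assert modes.loc[g] == expected
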