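import collections

import pytest

from gliascan.epitopes import EPITOPE_BY_NAME, census, scan_epitope
from gliascan.synthetic import (
    ConfigurationError,
    SyntheticConfig,
    generate_clone_library,
    generate_gene_family,
    plant_carriers,
)


class TestGeneFamily:
    def test_default_family_has_49_templates_split_18_12_19(self, default_family):
        _, genes, truth = default_family
        assert len(genes) == 49
        per_locus = collections.Counter(t.locus for t in truth.values())
        assert per_locus == {"Gli-A2": 18, "Gli-B2": 12, "Gli-D2": 19}

    def test_same_seed_gives_identical_fasta_bytes(self, tmp_path):
        from gliascan.seq_io import write_fasta

        paths = []
        for k in (1, 2):
            genes, _ = generate_gene_family(SyntheticConfig(seed=123))
            p = tmp_path / f"fam{k}.fasta"
            write_fasta(p, [(g.gene_id, g.orf) for g in genes])
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_different_seeds_differ(self):
        g1, _ = generate_gene_family(SyntheticConfig(seed=1))
        g2, _ = generate_gene_family(SyntheticConfig(seed=2))
        assert {g.orf for g in g1} != {g.orf for g in g2}

    def test_planted_marginals_recovered_by_independent_scan(self, default_family):
        """Carrier counts found by the scanner equal the configured
        marginals for every (locus, epitope) pair."""
        cfg, genes, _ = default_family
        table = census({g.gene_id: g.protein for g in genes})
        locus_of = {g.gene_id: g.locus for g in genes}
        found = collections.Counter()
        for gid in table.presence.index:
            for name in table.presence.columns:
                if table.presence.loc[gid, name]:
                    found[(locus_of[gid], name)] += 1
        for key, expected in cfg.planted_epitope_marginals.items():
            assert found.get(key, 0) == expected, key
        # and nothing was planted beyond the marginals
        assert set(found) <= set(
            k for k, v in cfg.planted_epitope_marginals.items() if v > 0)

    def test_targeted_planting_single_b2_gene(self):
        """Planting Glia-a9 in exactly one B-genome gene and no A-genome
        gene shows up identically in a downstream substring search."""
        cfg = SyntheticConfig()
        cfg.planted_epitope_marginals = {("Gli-B2", "Glia-a9"): 1}
        genes, truth = generate_gene_family(cfg)
        pep = EPITOPE_BY_NAME["Glia-a9"].peptide
        carriers = [g.gene_id for g in genes if scan_epitope(g.protein, pep)]
        assert len(carriers) == 1
        assert truth[carriers[0]].locus == "Gli-B2"

    def test_orf_lengths_span_printed_extremes(self, default_family):
        _, genes, _ = default_family
        lengths = sorted(len(g.orf) for g in genes)
        assert lengths[0] == 846 and lengths[-1] == 960
        assert all(846 <= n <= 960 for n in lengths)
        protein_lengths = sorted(len(g.protein) for g in genes)
        assert protein_lengths[0] == 281 and protein_lengths[-1] == 319

    def test_infeasible_marginal_exceeding_locus_size_rejected(self):
        cfg = SyntheticConfig()
        cfg.planted_epitope_marginals = dict(cfg.planted_epitope_marginals)
        cfg.planted_epitope_marginals[("Gli-B2", "Glia-a9")] = 13  # > 12 genes
        with pytest.raises(ConfigurationError):
            generate_gene_family(cfg)

    def test_contradictory_containment_marginals_rejected(self):
        # the 33-mer contains Glia-a2, so 4 carriers of the 33-mer cannot
        # coexist with fewer than 4 Glia-a2 carriers
        with pytest.raises(ConfigurationError, match="contradict"):
            plant_carriers(10, {"33-mer": 4, "Glia-a2": 2})

    def test_epitope_longer_than_hosting_domain_rejected(self):
        cfg = SyntheticConfig()
        cfg.domain_length_anchors = dict(cfg.domain_length_anchors)
        # Gli-D2 gene 1 carries the merged 58-residue repeat region; an
        # R1 of 40 residues cannot host it
        cfg.domain_length_anchors[("Gli-D2", 0)] = {"R1": 40}
        with pytest.raises(ConfigurationError, match="R1"):
            generate_gene_family(cfg)


class TestCloneLibrary:
    def test_published_library_sizes(self, noisy_libraries):
        _, libraries, _ = noisy_libraries
        assert {g: len(v) for g, v in libraries.items()} == {
            "Pegaso": 104, "dGliA2": 101, "dGliD2": 107, "dGliA2D2": 69}

    def test_every_clone_has_exactly_one_truth_label(self, noisy_libraries):
        _, libraries, clone_truth = noisy_libraries
        ids = [c.clone_id for clones in libraries.values() for c in clones]
        assert len(ids) == len(set(ids))
        assert set(ids) == set(clone_truth)
        assert all(t.label in ("faithful", "duplicate", "pseudogene", "chimera")
                   for t in clone_truth.values())

    def test_chimera_parents_are_distinct_and_co_sampled(self, noisy_libraries):
        _, libraries, clone_truth = noisy_libraries
        for t in clone_truth.values():
            if t.label == "chimera":
                p1, p2 = t.parents
                assert p1 != p2
                genotype_templates = {
                    clone_truth[c.clone_id].template_id
                    for c in libraries[t.genotype]
                    if clone_truth[c.clone_id].label in ("faithful", "duplicate")
                }
                assert {p1, p2} <= genotype_templates

    def test_libraries_sample_only_retained_loci(self, noisy_libraries, default_family):
        cfg, _, truth = default_family
        _, libraries, clone_truth = noisy_libraries
        for genotype, clones in libraries.items():
            retained = cfg.design.retains(genotype)
            for c in clones:
                t = clone_truth[c.clone_id]
                if t.template_id is not None:
                    assert truth[t.template_id].locus in retained

    def test_injected_chimera_count_matches_rate(self, default_family):
        _, _, truth = default_family
        cfg = SyntheticConfig(chimera_rate=0.1, pseudogene_rate=0.0)
        libraries, clone_truth = generate_clone_library(truth, cfg)
        n_chimeras = sum(t.label == "chimera" for t in clone_truth.values())
        expected = sum(round(0.1 * n) for n in cfg.clone_library_sizes.values())
        assert n_chimeras == expected

    def test_zero_noise_library_equals_retained_templates(self, zero_noise_libraries):
        cfg, _, truth, libraries, clone_truth = zero_noise_libraries
        for genotype, clones in libraries.items():
            retained = {t.orf for t in truth.values()
                        if t.locus in cfg.design.retains(genotype)}
            assert collections.Counter(c.sequence for c in clones) == \
                collections.Counter(retained)
            assert all(clone_truth[c.clone_id].label == "faithful" for c in clones)

    def test_empty_design_genotype_warns_and_yields_empty_library(self, default_family):
        from gliascan.records import GenotypeDesign

        cfg, _, truth = default_family
        cfg2 = SyntheticConfig(
            design=GenotypeDesign(
                retained={
                    "Pegaso": frozenset({"Gli-A2", "Gli-B2", "Gli-D2"}),
                    "nullline": frozenset(),
                },
                reference="Pegaso",
            ),
            clone_library_sizes={"Pegaso": 60, "nullline": 10},
        )
        with pytest.warns(UserWarning, match="nullline"):
            libraries, _ = generate_clone_library(truth, cfg2)
        assert libraries["nullline"] == []
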