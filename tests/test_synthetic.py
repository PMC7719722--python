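"""Generator contracts: realized counts, planted effects, determinism."""

import numpy as np
import pandas as pd
import pytest

from ncec import (
    ConfigurationError,
    ETSRP,
    GeneratorConfig,
    MUTANT_LABELS,
    NPAS4L,
    SOX32,
    WT,
    generate_ct_table,
    generate_expression_truth,
    generate_promoters,
    generate_spot_table,
)
from ncec.motif import reverse_complement
from ncec.synthetic import promoters_to_genome, write_spot_table

from conftest import make_tiny_cfg


class TestSpotTable:
    def test_default_counts_realized_exactly(self, default_cfg, default_chain):
        spots, truth = default_chain[0], default_chain[1]
        assert len(spots) == default_cfg.n_spots
        ident = spots["is_identifiable"] == 1
        assert int(ident.sum()) == default_cfg.n_identifiable
        passing = ident & (spots["detection_p"] < 0.5)
        assert int(passing.sum()) == default_cfg.n_pass_pvalue
        annotated = passing & (spots["is_control"] == 0) & (spots["gene_symbol"] != "NA")
        assert spots.loc[annotated, "gene_symbol"].nunique() == default_cfg.n_annotated_genes
        assert set(spots.loc[annotated, "gene_symbol"]) == set(truth.gene_ids)

    def test_degenerate_all_pass_config(self):
        cfg = make_tiny_cfg(
            n_spots=10,
            n_identifiable=10,
            n_pass_pvalue=10,
            n_control_pass=0,
            n_unannotated_pass=0,
            n_annotated_genes=10,
            n_non_endoderm=10,
            category_sizes={},
            shared_up=0,
            shared_down=0,
            unique_up_etsrp=0,
            unique_down_etsrp=0,
            unique_up_npas4l=0,
            unique_down_npas4l=0,
        )
        spots, _ = generate_spot_table(cfg)
        assert len(spots) == 10
        assert (spots["is_identifiable"] == 1).all()
        assert (spots["detection_p"] < 0.5).all()
        assert (spots["is_control"] == 0).all()
        assert spots["gene_symbol"].nunique() == 10

    def test_same_seed_byte_identical_different_seed_differs(self, tmp_path):
        cfg = make_tiny_cfg(seed=5)
        t1, _ = generate_spot_table(cfg)
        t2, _ = generate_spot_table(cfg)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_spot_table(t1, p1)
        write_spot_table(t2, p2)
        assert p1.read_bytes() == p2.read_bytes()
        t3, _ = generate_spot_table(make_tiny_cfg(seed=6))
        sample = [c for c in t1.columns if c.startswith("WT")][0]
        assert not np.array_equal(t1[sample].to_numpy(), t3[sample].to_numpy())

    @pytest.mark.parametrize(
        "overrides,fragment",
        [
            ({"n_pass_pvalue": 400, "n_identifiable": 350}, "n_pass_pvalue"),
            ({"n_identifiable": 500}, "n_identifiable"),
            ({"n_non_endoderm": 300}, "n_non_endoderm"),
            ({"n_control_pass": 300}, "n_annotated_genes"),
            ({"shared_up": -1}, "non-negative"),
            ({"replicate_noise_sd": -0.1}, "replicate_noise_sd"),
            ({"category_sizes": {"angiogenesis": 999}}, "category_sizes"),
        ],
    )
    def test_inconsistent_configs_raise_naming_constraint(self, overrides, fragment):
        with pytest.raises(ConfigurationError, match=fragment):
            generate_spot_table(make_tiny_cfg(**overrides))


class TestExpressionTruth:
    def test_planted_ratios_exact_without_noise(self, noisefree_expr):
        cfg, m, truth = noisefree_expr
        log2m = np.log2(m.values)
        for mutant in MUTANT_LABELS:
            ratio = (
                log2m[m.columns_for(mutant)].mean(axis=1)
                - log2m[m.columns_for(WT)].mean(axis=1)
            )
            up, down = truth.deg_up[mutant], truth.deg_down[mutant]
            assert np.allclose(ratio[list(up)], cfg.deg_effect_log2, atol=1e-9)
            assert np.allclose(ratio[list(down)], -cfg.deg_effect_log2, atol=1e-9)
        endo = list(truth.endoderm_gene_ids)
        contrast = (
            log2m[m.columns_for(WT)].mean(axis=1)
            - log2m[m.columns_for(SOX32)].mean(axis=1)
        )
        assert np.allclose(contrast[endo], np.log2(cfg.endoderm_fold), atol=1e-9)
        non_endo = list(truth.non_endoderm_gene_ids)
        assert np.allclose(contrast[non_endo], 0.0, atol=1e-9)

    def test_null_configuration_gives_identical_genotypes(self):
        cfg = make_tiny_cfg(
            shared_up=0,
            shared_down=0,
            unique_up_etsrp=0,
            unique_down_etsrp=0,
            unique_up_npas4l=0,
            unique_down_npas4l=0,
            deg_effect_log2=0.0,
            endoderm_fold=1.0,
            category_rank_noise={},
            replicate_noise_sd=0.0,
        )
        m, _ = generate_expression_truth(cfg)
        ref = m.values[m.columns_for(WT)[0]]
        for col in m.samples:
            assert np.allclose(m.values[col], ref, atol=0)

    def test_zero_replicate_noise_yields_identical_replicates(self, noisefree_expr):
        _, m, _ = noisefree_expr
        for genotype in m.genotypes:
            cols = m.columns_for(genotype)
            for col in cols[1:]:
                assert np.array_equal(
                    m.values[col].to_numpy(), m.values[cols[0]].to_numpy()
                )

    def test_truth_sets_consistent(self, noisefree_expr):
        _, m, truth = noisefree_expr
        universe = set(truth.gene_ids)
        assert set(m.gene_ids) == universe
        for mutant in MUTANT_LABELS:
            assert not truth.deg_up[mutant] & truth.deg_down[mutant]
            assert truth.shared_up_ids <= truth.deg_up[mutant]
            assert truth.shared_down_ids <= truth.deg_down[mutant]
            assert not (truth.deg_up[mutant] | truth.deg_down[mutant]) & truth.endoderm_gene_ids
        assert set(truth.category_of_gene) <= universe

    def test_category_noise_restricted_to_mutants(self):
        # with zero replicate noise and no DEGs, perturbation appears only in
        # the avascular mutants and only within the named category
        cfg = make_tiny_cfg(
            shared_up=0, shared_down=0,
            unique_up_etsrp=0, unique_down_etsrp=0,
            unique_up_npas4l=0, unique_down_npas4l=0,
            replicate_noise_sd=0.0, endoderm_fold=1.0,
            category_rank_noise={"somitogenesis": 1.0},
        )
        m, truth = generate_expression_truth(cfg)
        log2m = np.log2(m.values)
        wt = log2m[m.columns_for(WT)].mean(axis=1)
        sox = log2m[m.columns_for(SOX32)].mean(axis=1)
        assert np.allclose(wt, sox, atol=1e-9)
        for mutant in MUTANT_LABELS:
            delta = (log2m[m.columns_for(mutant)].mean(axis=1) - wt).abs()
            somito = [g for g, c in truth.category_of_gene.items() if c == "somitogenesis"]
            untouched = [g for g in truth.gene_ids if g not in somito]
            assert np.allclose(delta[untouched], 0.0, atol=1e-9)
            assert delta[somito].max() > 0


class TestPromoters:
    def test_planted_presence_and_absence(self, tiny_cfg):
        promoters, truth = generate_promoters(tiny_cfg)
        motif, rc = "TCGTGA", reverse_complement("TCGTGA")
        assert len(truth.motif_positive_genes) == tiny_cfg.n_motif_positive
        assert len(truth.motif_negative_genes) == tiny_cfg.n_motif_negative
        for gene in truth.motif_positive_genes:
            assert motif in promoters[gene] or rc in promoters[gene]
        for gene in truth.motif_negative_genes:
            assert motif not in promoters[gene]
            assert rc not in promoters[gene]

    def test_zero_positive_genes(self, tiny_cfg):
        cfg = tiny_cfg.replace(n_motif_positive=0)
        promoters, truth = generate_promoters(cfg)
        assert truth.motif_positive_genes == frozenset()
        for seq in promoters.values():
            assert "TCGTGA" not in seq and "TCACGA" not in seq

    def test_promoter_shorter_than_motif_rejected(self, tiny_cfg):
        with pytest.raises(ConfigurationError, match="promoter_length"):
            generate_promoters(tiny_cfg.replace(promoter_length=5))

    def test_genome_embedding_roundtrip(self, tiny_cfg):
        from ncec.motif import extract_promoters

        promoters, _ = generate_promoters(tiny_cfg)
        genome, bed = promoters_to_genome(promoters, upstream=tiny_cfg.promoter_length)
        extracted = extract_promoters(
            bed, genome, upstream=tiny_cfg.promoter_length, downstream=0
        )
        assert extracted.sequences == promoters


class TestCtTable:
    def test_structure_and_planted_shift(self, tiny_cfg):
        table, _ = generate_ct_table(tiny_cfg.replace(ct_noise_sd=0.0))
        assert set(table.columns) == {"gene", "condition", "replicate", "ct"}
        piv = table.groupby(["gene", "condition"])["ct"].mean()
        for ref in ("18S_rRNA", "kdrl"):
            assert piv[(ref, "control")] == piv[(ref, "npas4l_MO")]
        for gene, fold in tiny_cfg.ct_folds.items():
            shift = piv[(gene, "control")] - piv[(gene, "npas4l_MO")]
            assert shift == pytest.approx(np.log2(fold), abs=1e-12)
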