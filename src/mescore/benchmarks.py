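"""End-to-end validation benchmarks on synthetic communities.

Each function runs the full pipeline on seeded synthetic data with a
known planted truth and returns ``{"value": ..., "n": ...}`` — a
recovery rate, an error rate, or an agreement fraction.  They back both
the validation test suite and ``scripts/acceptance.py``, so the numbers
reported there are always recomputed from scratch.

All problem sizes (species pools, cohort sizes, seed counts) are the
package's simulation study conditions; see ``docs/methods.md``.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd

from mescore import cohort_stats, flux_attribution, gene_association, mes_core
from mescore import producer_consumer, richness_slopes, synthetic_data
from mescore.synthetic_data import CommunitySpec, EffectSpec, GeneLinkage


def _child_seeds(seed: int, n: int) -> list[int]:
    """n reproducible sub-seeds below 2**31 derived from one master seed."""
    return [int(s) for s in np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)]


def mes_exhaustive(max_count: int = 100) -> dict:
    """Fraction of the (P, C) grid where mes() matches exact rational arithmetic."""
    agree = 0
    total = 0
    for P in range(max_count + 1):
        for C in range(max_count + 1):
            expected = 0.0 if (P == 0 or C == 0) else float(2 * Fraction(P * C, P + C))
            agree += mes_core.mes(P, C) == expected
            total += 1
    return {"value": agree / total, "n": total}


def brute_force_mes(records: pd.DataFrame, tolerance: float = 1e-6) -> dict:
    """Independent per-record recount of every (sample, metabolite) MES.

    Scans records one at a time into plain producer/consumer sets and
    applies the harmonic-mean formula; shares no code path with
    extract_sets / mes_matrix.
    """
    producers: dict = {}
    consumers: dict = {}
    for row in records.itertuples(index=False):
        if row.flux <= tolerance:
            continue
        key = (row.sample_id, row.metabolite_id)
        target = producers if row.direction == "export" else consumers
        target.setdefault(key, set()).add(row.taxon_id)
    out = {}
    for key in set(producers) | set(consumers):
        P = len(producers.get(key, set()))
        C = len(consumers.get(key, set()))
        out[key] = 0.0 if (P == 0 or C == 0) else 2.0 * P * C / (P + C)
    return out


def mes_matrix_oracle(seed: int, n_samples: int = 200) -> dict:
    """Exact-agreement fraction between the pipeline MES matrix and the recount."""
    spec = CommunitySpec(n_species=80, n_metabolites=20, richness_range=(20, 80))
    dataset = synthetic_data.generate(spec, [], {"healthy": n_samples}, seed=seed)
    sets = producer_consumer.extract_sets(dataset.records)
    matrix = mes_core.mes_matrix(sets)
    pipeline = {
        (r.sample_id, r.metabolite_id): r.mes for r in matrix.itertuples(index=False)
    }
    oracle = brute_force_mes(dataset.records)
    keys = set(pipeline) | set(oracle)
    agree = sum(pipeline.get(k) == oracle.get(k) for k in keys)
    return {"value": agree / len(keys), "n": len(keys)}


def _loss_spec(n_metabolites: int = 30) -> CommunitySpec:
    return CommunitySpec(
        n_species=150, n_metabolites=n_metabolites, richness_range=(34, 150)
    )


def planted_loss_recovery(
    seed: int,
    n_seeds: int = 20,
    consumer_loss_fraction: float = 0.5,
    n_per_cohort: int = 40,
) -> dict:
    """Rate at which a planted consumer loss tops the MES-loss ranking.

    One of 30 metabolites loses half its consumer species in the disease
    cohort (40 vs 40 samples); success requires that metabolite to rank
    #1 by MES delta among significant reductions after Bonferroni.
    """
    target = "m005"
    hits = 0
    for s in _child_seeds(seed, n_seeds):
        effect = EffectSpec(
            metabolite=target, cohort="disease",
            consumer_loss_fraction=consumer_loss_fraction,
        )
        dataset = synthetic_data.generate(
            _loss_spec(), [effect],
            {"healthy": n_per_cohort, "disease": n_per_cohort}, seed=s,
        )
        matrix = mes_core.mes_matrix(producer_consumer.extract_sets(dataset.records))
        mets = cohort_stats.filter_metabolites(matrix, dataset.metadata, "disease")
        results = cohort_stats.test_mes_difference(
            matrix, dataset.metadata, "disease", mets
        )
        top = cohort_stats.rank_losses(results, k=1)
        hits += (not top.empty) and top["metabolite_id"].iloc[0] == target
    return {"value": hits / n_seeds, "n": n_seeds}


def null_familywise_error(
    seed: int, n_seeds: int = 20, n_metabolites: int = 300, n_per_cohort: int = 40
) -> dict:
    """Fraction of null test families flagging any metabolite as significant.

    No effect is planted, so with Bonferroni control at alpha = 0.05 the
    fraction should stay at or below 0.05 up to binomial error.
    """
    families_with_hit = 0
    for s in _child_seeds(seed, n_seeds):
        dataset = synthetic_data.generate(
            _loss_spec(n_metabolites), [],
            {"healthy": n_per_cohort, "disease": n_per_cohort}, seed=s,
        )
        matrix = mes_core.mes_matrix(producer_consumer.extract_sets(dataset.records))
        mets = cohort_stats.filter_metabolites(matrix, dataset.metadata, "disease")
        results = cohort_stats.test_mes_difference(
            matrix, dataset.metadata, "disease", mets, one_sided_mode="halve"
        )
        families_with_hit += bool(results["significant"].any())
    return {"value": families_with_hit / n_seeds, "n": n_seeds}


def slope_recovery(
    seed: int,
    n_seeds: int = 20,
    producer_slope: float = 0.05,
    consumer_slope: float = 0.15,
    n_samples: int = 200,
) -> dict:
    """Rate of consumer_steeper classification for a planted slope gap.

    The target metabolite's producer/consumer capability densities are the
    planted per-richness-unit slopes (counts are binomial in richness, so
    the expected count is density × richness).
    """
    n_met = 20
    target_idx = 0
    prod_density = np.full(n_met, 0.15)
    cons_density = np.full(n_met, 0.2)
    prod_density[target_idx] = producer_slope
    cons_density[target_idx] = consumer_slope
    spec = CommunitySpec(
        n_species=240, n_metabolites=n_met,
        producer_density=list(prod_density), consumer_density=list(cons_density),
        dual_density=0.0, richness_range=(34, 236),
    )
    target = spec.metabolites()[target_idx]
    hits = 0
    for s in _child_seeds(seed, n_seeds):
        dataset = synthetic_data.generate(spec, [], {"healthy": n_samples}, seed=s)
        sets = producer_consumer.extract_sets(dataset.records)
        adiv = cohort_stats.alpha_diversity(dataset.abundance)
        long_table = richness_slopes.build_long_table(sets, adiv)
        fits = richness_slopes.fit_interactions(long_table)
        row = fits[fits["metabolite_id"] == target]
        hits += (not row.empty) and row["classification"].iloc[0] == "consumer_steeper"
    return {"value": hits / n_seeds, "n": n_seeds}


def key_species_recovery(seed: int, n_seeds: int = 20, factor: float = 0.2) -> dict:
    """Rate at which a planted per-species consumer flux deficit ranks #1.

    The consumer taxon with the largest baseline weighted flux sum for the
    target metabolite has its consumption fluxes scaled by ``factor`` (a
    5× deficit at the default) in the disease cohort; success means it
    tops the consumer delta ranking after cohort balancing (46 vs 38
    samples down-sampled to 38/38).
    """
    target = "m003"
    n = {"healthy": 46, "disease": 38}
    hits = 0
    for s in _child_seeds(seed, n_seeds):
        spec = _loss_spec()
        baseline = synthetic_data.generate(spec, [], n, seed=s)
        balanced = flux_attribution.balance_cohorts(
            baseline.metadata, ("healthy", "disease"), seed=s
        )
        healthy = balanced.index[balanced["cohort"] == "healthy"]
        sums = flux_attribution.weighted_flux_sums(
            baseline.records, baseline.abundance, healthy, target
        )
        consumers = sums[sums["role"] == "consumer"]
        planted = consumers.loc[consumers["weighted_sum"].idxmax(), "taxon_id"]
        effect = EffectSpec(
            metabolite=target, cohort="disease",
            species_flux_factors={planted: {"consumer": factor}},
        )
        dataset = synthetic_data.generate(spec, [effect], n, seed=s)
        key = flux_attribution.key_species(
            dataset.records, dataset.abundance, dataset.metadata,
            target, ("healthy", "disease"), top_n=5, seed=s,
        )
        top_consumer = key[key["role"] == "consumer"].iloc[0]["taxon_id"]
        hits += top_consumer == planted
    return {"value": hits / n_seeds, "n": n_seeds}


def gene_recovery(
    seed: int, n_seeds: int = 20, p_linked: float = 0.9, p_background: float = 0.1
) -> dict:
    """Rate of correct, significant healthy-enrichment for a role-linked gene.

    The focal gene rides on consumer species of the target metabolite;
    half of those species are removed from the disease cohort's
    communities, so the gene should test as enriched in healthy.  Four
    unlinked background genes pad the Bonferroni family.
    """
    target = "m005"
    linkages = [GeneLinkage("geneA", "consumer", target, p_linked, p_background)] + [
        GeneLinkage(f"bg{i}", "consumer", target, 0.2, 0.2) for i in range(4)
    ]
    hits = 0
    for s in _child_seeds(seed, n_seeds):
        effect = EffectSpec(
            metabolite=target, cohort="disease",
            consumer_loss_fraction=0.5, remove_lost_species=True,
        )
        dataset = synthetic_data.generate(
            _loss_spec(), [effect], {"healthy": 40, "disease": 40}, seed=s
        )
        gene_hits = synthetic_data.generate_gene_hits(dataset, linkages, seed=s)
        values = gene_association.gene_sample_matrix(
            gene_hits, dataset.abundance, "prevalence"
        )
        adiv = cohort_stats.alpha_diversity(dataset.abundance)
        results, _ = gene_association.test_genes(
            values, dataset.metadata, adiv, disease="disease",
            mode="prevalence", min_species=34,
        )
        row = results[results["gene_id"] == "geneA"]
        hits += (
            (not row.empty)
            and bool(row["significant"].iloc[0])
            and row["enriched_in"].iloc[0] == "healthy"
        )
    return {"value": hits / n_seeds, "n": n_seeds}


def gene_null_familywise_error(seed: int, n_seeds: int = 20) -> dict:
    """Family-wise false-positive rate under a null gene assignment.

    Gene carriage is independent of cohort (uniform probability, no
    planted community effect), so with Bonferroni control no family
    should flag a gene beyond the alpha rate.
    """
    target = "m005"
    linkages = [GeneLinkage(f"g{i}", "consumer", target, 0.2, 0.2) for i in range(10)]
    families_with_hit = 0
    for s in _child_seeds(seed, n_seeds):
        dataset = synthetic_data.generate(
            _loss_spec(), [], {"healthy": 40, "disease": 40}, seed=s
        )
        gene_hits = synthetic_data.generate_gene_hits(dataset, linkages, seed=s)
        values = gene_association.gene_sample_matrix(
            gene_hits, dataset.abundance, "prevalence"
        )
        adiv = cohort_stats.alpha_diversity(dataset.abundance)
        results, _ = gene_association.test_genes(
            values, dataset.metadata, adiv, disease="disease",
            mode="prevalence", min_species=34,
        )
        families_with_hit += bool(results["significant"].any())
    return {"value": families_with_hit / n_seeds, "n": n_seeds}


def cli_determinism(seed: int) -> dict:
    """Fraction of CLI subcommands whose reruns are byte-identical.

    Runs every subcommand twice with identical arguments in temporary
    directories (simulate with a planted effect and a gene linkage, then
    mes / compare / slopes / attribute / genes on its outputs) and
    compares every produced file byte for byte.
    """
    import tempfile
    from pathlib import Path

    from click.testing import CliRunner

    from mescore.cli import main as cli_main

    config = f"""
spec:
  n_species: 80
  n_metabolites: 10
  richness_range: [20, 80]
effects:
  - metabolite: m002
    cohort: disease
    consumer_loss_fraction: 0.5
n_samples:
  healthy: 15
  disease: 15
gene_linkages:
  - gene_id: geneA
    role: consumer
    metabolite: m002
"""
    runner = CliRunner()
    identical = 0
    subcommands = ["simulate", "mes", "compare", "slopes", "attribute", "genes"]
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        cfg = tmp / "config.yaml"
        cfg.write_text(config)

        def run_all(base: Path) -> None:
            sim = base / "sim"
            argsets = {
                "simulate": ["simulate", "--config", str(cfg), "--seed", str(seed),
                             "--out", str(sim)],
                "mes": ["mes", "--flux", str(sim / "flux.tsv"),
                        "--out", str(base / "mes")],
                "compare": ["compare", "--flux", str(sim / "flux.tsv"),
                            "--metadata", str(sim / "metadata.tsv"),
                            "--abundance", str(sim / "abundance.tsv"),
                            "--min-total", "10", "--min-diseased", "3",
                            "--out", str(base / "compare")],
                "slopes": ["slopes", "--flux", str(sim / "flux.tsv"),
                           "--abundance", str(sim / "abundance.tsv"),
                           "--min-samples", "10", "--out", str(base / "slopes")],
                "attribute": ["attribute", "--flux", str(sim / "flux.tsv"),
                              "--abundance", str(sim / "abundance.tsv"),
                              "--metadata", str(sim / "metadata.tsv"),
                              "--metabolite", "m002",
                              "--cohorts", "healthy,disease",
                              "--seed", str(seed), "--min-species", "20",
                              "--out", str(base / "attribute")],
                "genes": ["genes", "--gene-hits", str(sim / "gene_hits.tsv"),
                          "--abundance", str(sim / "abundance.tsv"),
                          "--metadata", str(sim / "metadata.tsv"),
                          "--disease", "disease", "--min-species", "20",
                          "--min-samples-with-gene", "3",
                          "--out", str(base / "genes")],
            }
            for name in subcommands:
                result = runner.invoke(cli_main, argsets[name], catch_exceptions=False)
                assert result.exit_code == 0, f"{name} failed: {result.output}"

        run_all(tmp / "run1")
        run_all(tmp / "run2")
        for sub in ["sim", "mes", "compare", "slopes", "attribute", "genes"]:
            d1, d2 = tmp / "run1" / sub, tmp / "run2" / sub
            if not d1.is_dir():
                d1, d2 = tmp / "run1" / "sim", tmp / "run2" / "sim"
            files1 = sorted(p.name for p in d1.iterdir())
            files2 = sorted(p.name for p in d2.iterdir())
            identical += files1 == files2 and all(
                (d1 / f).read_bytes() == (d2 / f).read_bytes() for f in files1
            )
    return {"value": identical / len(subcommands), "n": len(subcommands)}
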