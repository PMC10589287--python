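"""Seeded synthetic microbiome flux simulator with known ground truth.

Emulates the statistical shape of community-FBA "growth workflow"
outputs: a species pool with per-metabolite producer/consumer
capabilities, per-sample communities of varying richness, lognormal
relative abundances and exchange-flux magnitudes, and plantable cohort
effects — selective loss of a metabolite's consumer (or producer)
species in a disease cohort, flux scaling per role, and per-species
flux deficits.  Every planted truth lands in a manifest so downstream
recovery can be checked against it.

No mass balance or genome-scale metabolism is simulated; fluxes are
statistical stand-ins with the right layout and dynamic range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import json

import numpy as np
import pandas as pd

from mescore.errors import GenerationError
from mescore.flux_io import renormalize_abundance, write_table


@dataclass
class CommunitySpec:
    """Ground-truth parameters of the simulated species pool and samples.

    Capability densities are the probabilities that a species is,
    for a given metabolite, a producer only, a consumer only, or both
    (dual-role); each may be a scalar or a per-metabolite array.
    Richness (community size per sample) is uniform on
    ``richness_range``, clipped to the pool size.  Flux magnitudes
    (mmol·gDW⁻¹·h⁻¹) and raw abundances are lognormal.
    """

    n_species: int = 150
    n_metabolites: int = 60
    producer_density: float | list = 0.15
    consumer_density: float | list = 0.2
    dual_density: float | list = 0.05
    flux_mu: float = 0.0
    flux_sigma: float = 1.0
    abundance_mu: float = 0.0
    abundance_sigma: float = 1.5
    richness_range: tuple[int, int] = (34, 236)
    metabolite_ids: list[str] | None = None

    def metabolites(self) -> list[str]:
        if self.metabolite_ids is not None:
            if len(self.metabolite_ids) != self.n_metabolites:
                raise ValueError("metabolite_ids length must equal n_metabolites")
            return list(self.metabolite_ids)
        return [f"m{i:03d}" for i in range(self.n_metabolites)]

    def species(self) -> list[str]:
        return [f"sp{i:03d}" for i in range(self.n_species)]


@dataclass
class EffectSpec:
    """A planted cohort effect on one metabolite.

    ``consumer_loss_fraction`` / ``producer_loss_fraction`` remove that
    fraction of the metabolite's capable species (species-level: the lost
    species lacks the capability in every sample of the affected cohort,
    mimicking disease-associated extinction of cross-feeding partners).
    With ``remove_lost_species`` the lost species drop out of the
    cohort's communities entirely (abundances renormalized), which also
    shifts any species-linked signal such as gene carriage.  Flux factors
    scale the surviving records' magnitudes per role;
    ``species_flux_factors`` maps taxon id → {role: factor} for
    single-species deficits.  The identity effect (fractions 0, factors
    1) reproduces the null byte-for-byte.
    """

    metabolite: str
    cohort: str
    consumer_loss_fraction: float = 0.0
    producer_loss_fraction: float = 0.0
    flux_factor_producers: float = 1.0
    flux_factor_consumers: float = 1.0
    remove_lost_species: bool = False
    species_flux_factors: dict = field(default_factory=dict)


@dataclass
class SyntheticDataset:
    """In-memory result of :func:`generate`, plus a writer."""

    records: pd.DataFrame
    abundance: pd.DataFrame
    metadata: pd.DataFrame
    manifest: dict
    prod_capability: pd.DataFrame
    cons_capability: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        """Write flux/abundance/metadata TSVs plus the manifest JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        flux = self.records.rename(columns={"taxon_id": "taxon", "metabolite_id": "metabolite"})
        write_table(flux, outdir / "flux.tsv", float_format=None)
        ab = self.abundance.reset_index().rename(columns={"index": "sample_id"})
        ab.columns = ["sample_id", *self.abundance.columns]
        write_table(ab, outdir / "abundance.tsv", float_format=None)
        meta = self.metadata.reset_index()
        write_table(meta, outdir / "metadata.tsv", float_format=None)
        (outdir / "ground_truth.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True) + "\n"
        )


def _broadcast(density, n: int) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(density, dtype=float), (n,)).copy()
    if (arr < 0).any() or (arr > 1).any():
        raise ValueError("capability densities must lie in [0, 1]")
    return arr


def _draw_capabilities(spec: CommunitySpec, rng: np.random.Generator):
    """Role matrices (species × metabolite); every metabolite keeps ≥1 of each role."""
    n_sp, n_met = spec.n_species, spec.n_metabolites
    d_dual = _broadcast(spec.dual_density, n_met)
    d_prod = _broadcast(spec.producer_density, n_met)
    d_cons = _broadcast(spec.consumer_density, n_met)
    if ((d_dual + d_prod + d_cons) > 1).any():
        raise ValueError("capability densities sum to more than 1 for some metabolite")
    prod = np.zeros((n_sp, n_met), dtype=bool)
    cons = np.zeros((n_sp, n_met), dtype=bool)
    todo = np.arange(n_met)
    for _ in range(100):
        u = rng.random((n_sp, len(todo)))
        both = u < d_dual[todo]
        p_only = (u >= d_dual[todo]) & (u < (d_dual + d_prod)[todo])
        c_only = (u >= (d_dual + d_prod)[todo]) & (u < (d_dual + d_prod + d_cons)[todo])
        prod[:, todo] = both | p_only
        cons[:, todo] = both | c_only
        ok = prod[:, todo].any(axis=0) & cons[:, todo].any(axis=0)
        todo = todo[~ok]
        if todo.size == 0:
            return prod, cons
    raise GenerationError(
        "could not realize ≥1 producer and ≥1 consumer per metabolite; "
        "densities too low for the species pool"
    )


def generate(
    spec: CommunitySpec,
    effects: list[EffectSpec] | None = None,
    n_samples: dict[str, int] | None = None,
    seed: int = 0,
) -> SyntheticDataset:
    """Simulate flux, abundance and metadata tables with planted effects.

    Parameters
    ----------
    spec
        Pool and distribution parameters.
    effects
        Planted cohort effects; empty or identity effects give the null.
    n_samples
        Mapping cohort label → number of samples, e.g.
        ``{"healthy": 40, "cd": 40}``.
    seed
        Single source of randomness; identical (spec, effects, n_samples,
        seed) reproduce byte-identical outputs.
    """
    effects = effects or []
    n_samples = n_samples or {"healthy": 40, "disease": 40}
    rng = np.random.default_rng(seed)
    species = spec.species()
    metabolites = spec.metabolites()
    met_index = {m: j for j, m in enumerate(metabolites)}
    n_sp = spec.n_species

    prod_pool, cons_pool = _draw_capabilities(spec, rng)

    # cohort-effective capabilities start as the pool realization
    cohorts = list(n_samples)
    prod_eff = {c: prod_pool for c in cohorts}
    cons_eff = {c: cons_pool for c in cohorts}
    removed_species: dict[str, set[int]] = {c: set() for c in cohorts}
    effect_log = []
    for eff in effects:
        if eff.metabolite not in met_index:
            raise ValueError(f"effect targets unknown metabolite {eff.metabolite!r}")
        if eff.cohort not in n_samples:
            raise ValueError(f"effect targets unknown cohort {eff.cohort!r}")
        j = met_index[eff.metabolite]
        entry = {"removed_consumers": [], "removed_producers": []}
        for fraction, pool, eff_map, key in (
            (eff.consumer_loss_fraction, cons_pool, cons_eff, "removed_consumers"),
            (eff.producer_loss_fraction, prod_pool, prod_eff, "removed_producers"),
        ):
            if not 0.0 <= fraction <= 1.0:
                raise ValueError("loss fractions must lie in [0, 1]")
            candidates = np.flatnonzero(pool[:, j])
            n_lost = int(round(fraction * len(candidates)))
            if n_lost == 0:
                continue
            if n_lost >= len(candidates):
                raise GenerationError(
                    f"effect on {eff.metabolite!r} would leave no "
                    f"{key.split('_')[1][:-1]} species in cohort {eff.cohort!r}"
                )
            lost = np.sort(rng.choice(candidates, size=n_lost, replace=False))
            mat = eff_map[eff.cohort].copy()
            mat[lost, j] = False
            eff_map[eff.cohort] = mat
            entry[key] = [species[i] for i in lost]
            if eff.remove_lost_species:
                removed_species[eff.cohort].update(int(i) for i in lost)
        effect_log.append({**asdict(eff), **entry})

    # per-sample communities
    lo, hi = spec.richness_range
    hi = min(hi, n_sp)
    if lo > hi:
        raise ValueError("richness_range lower bound exceeds the species pool size")
    sample_ids, cohort_labels = [], []
    for cohort in cohorts:
        for i in range(n_samples[cohort]):
            sample_ids.append(f"s{len(sample_ids):04d}")
            cohort_labels.append(cohort)
    n_total = len(sample_ids)
    presence = np.zeros((n_total, n_sp), dtype=bool)
    abundance = np.zeros((n_total, n_sp), dtype=float)
    richness_draws = rng.integers(lo, hi + 1, size=n_total)
    for i in range(n_total):
        chosen = rng.choice(n_sp, size=richness_draws[i], replace=False)
        presence[i, chosen] = True
        raw = rng.lognormal(spec.abundance_mu, spec.abundance_sigma, size=len(chosen))
        abundance[i, chosen] = raw
    presence_pre = presence.copy()
    for cohort, lost in removed_species.items():
        if not lost:
            continue
        rows = [i for i, c in enumerate(cohort_labels) if c == cohort]
        cols = sorted(lost)
        presence[np.ix_(rows, cols)] = False
        abundance[np.ix_(rows, cols)] = 0.0
        if not presence[rows].any(axis=1).all():
            raise GenerationError(
                f"species removal emptied a sample in cohort {cohort!r}"
            )
    abundance /= abundance.sum(axis=1, keepdims=True)

    # flux records: one per (sample, capable present species, metabolite, role)
    cohort_idx = np.array([cohorts.index(c) for c in cohort_labels])
    frames = []
    for direction, eff_map in (("export", prod_eff), ("import", cons_eff)):
        cap_stack = np.stack([eff_map[c] for c in cohorts])  # cohort × sp × met
        mask = presence[:, :, None] & cap_stack[cohort_idx]
        si, spi, mi = np.nonzero(mask)
        flux = rng.lognormal(spec.flux_mu, spec.flux_sigma, size=len(si))
        for eff in effects:
            j = met_index[eff.metabolite]
            in_cohort = np.array(
                [cohort_labels[i] == eff.cohort for i in si], dtype=bool
            )
            factor = (
                eff.flux_factor_producers
                if direction == "export"
                else eff.flux_factor_consumers
            )
            sel = in_cohort & (mi == j)
            if factor != 1.0:
                flux[sel] *= factor
            for taxon, role_factors in eff.species_flux_factors.items():
                role = "producer" if direction == "export" else "consumer"
                f = role_factors.get(role, 1.0)
                if f != 1.0:
                    sp_j = species.index(taxon)
                    flux[sel & (spi == sp_j)] *= f
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": np.array(sample_ids)[si],
                    "taxon_id": np.array(species)[spi],
                    "metabolite_id": np.array(metabolites)[mi],
                    "direction": direction,
                    "flux": flux,
                }
            )
        )
    records = pd.concat(frames, ignore_index=True)
    records = records.sort_values(
        ["sample_id", "taxon_id", "metabolite_id", "direction"], kind="mergesort"
    ).reset_index(drop=True)

    abundance_df = pd.DataFrame(abundance, index=pd.Index(sample_ids, name="sample_id"),
                                columns=species)
    abundance_df = renormalize_abundance(abundance_df)
    metadata = pd.DataFrame(
        {"cohort": cohort_labels, "study_id": "synthetic"},
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # ground truth counts, post- and pre-effect
    def counts(pres, prod_map, cons_map):
        P = np.stack(
            [pres[i].astype(int) @ prod_map[cohort_labels[i]].astype(int)
             for i in range(n_total)]
        )
        C = np.stack(
            [pres[i].astype(int) @ cons_map[cohort_labels[i]].astype(int)
             for i in range(n_total)]
        )
        return P, C

    P_true, C_true = counts(presence, prod_eff, cons_eff)
    pool_maps = ({c: prod_pool for c in cohorts}, {c: cons_pool for c in cohorts})
    P_pre, C_pre = counts(presence_pre, *pool_maps)

    d_dual = _broadcast(spec.dual_density, spec.n_metabolites)
    manifest = {
        "seed": seed,
        "n_samples": dict(n_samples),
        "spec": {**asdict(spec), "richness_range": [lo, hi]},
        "effects": effect_log,
        "true_counts": {
            "samples": sample_ids,
            "metabolites": metabolites,
            "P": P_true.tolist(),
            "C": C_true.tolist(),
        },
        "true_counts_pre_effect": {"P": P_pre.tolist(), "C": C_pre.tolist()},
        "slope_truth": {
            "producer_density": (
                _broadcast(spec.producer_density, spec.n_metabolites) + d_dual
            ).tolist(),
            "consumer_density": (
                _broadcast(spec.consumer_density, spec.n_metabolites) + d_dual
            ).tolist(),
        },
        "key_species": {
            taxon: factors
            for eff in effects
            for taxon, factors in eff.species_flux_factors.items()
        },
    }
    return SyntheticDataset(
        records=records,
        abundance=abundance_df,
        metadata=metadata,
        manifest=manifest,
        prod_capability=pd.DataFrame(prod_pool, index=species, columns=metabolites),
        cons_capability=pd.DataFrame(cons_pool, index=species, columns=metabolites),
    )


@dataclass
class GeneLinkage:
    """Carriage rule tying a gene to a metabolic role.

    Species with the stated role capability for ``metabolite`` carry the
    gene with probability ``p_linked``; all others with ``p_background``.
    Copy number is 1 plus a Poisson(``extra_copy_rate``) draw.
    """

    gene_id: str
    role: str  # "producer" or "consumer"
    metabolite: str
    p_linked: float = 0.9
    p_background: float = 0.1
    extra_copy_rate: float = 0.5


def generate_gene_hits(
    dataset: SyntheticDataset, linkages: list[GeneLinkage], seed: int = 0
) -> pd.DataFrame:
    """Per-taxon gene copy counts tied to pool-level role capabilities."""
    rng = np.random.default_rng(seed)
    rows = []
    for link in linkages:
        cap = dataset.cons_capability if link.role == "consumer" else dataset.prod_capability
        if link.metabolite not in cap.columns:
            raise ValueError(f"linkage targets unknown metabolite {link.metabolite!r}")
        linked = cap[link.metabolite].to_numpy(dtype=bool)
        prob = np.where(linked, link.p_linked, link.p_background)
        carried = rng.random(len(prob)) < prob
        copies = np.where(carried, 1 + rng.poisson(link.extra_copy_rate, len(prob)), 0)
        for taxon, c in zip(cap.index, copies):
            if c > 0:
                rows.append((taxon, link.gene_id, int(c)))
    return pd.DataFrame(rows, columns=["taxon_id", "gene_id", "copies"])
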