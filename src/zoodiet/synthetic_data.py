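"""Synthetic gut/water metabarcoding datasets with known selectivity ground truth.

The generator emulates a multi-station plankton diet survey: each station
and campaign has a latent water community ``w`` (drawn from a station
Dirichlet), sampled by three water replicates; each predator carries a
selectivity vector ``alpha`` on the simplex and its gut composition follows
Chesson mixing,

    p_i = alpha_i * w_i / sum_k alpha_k * w_k,

sampled by five gut replicates (each standing for a pool of five
individuals).  Chesson mixing makes the standardized forage ratio the exact
inverse of the generator: applied to noise-free compositions it returns
``alpha`` identically, which gives closed-form recovery tests.

Reads are multinomial (optionally Dirichlet-multinomial) draws at the
configured library sizes.  Gut samples additionally carry contaminant read
classes appended as extra taxa — predator (crustacean) reads, heterotrophic
bacteria, and an euglenozoan epibiont — whose lineages match the standard
exclusion rules.  Contaminant reads are added on top of the prey reads (the
library size budgets the prey reads), so a contaminated simulation and its
contaminant-free twin share identical prey counts under the same seed.

Randomness: one root seed; every sample draws from a substream derived
deterministically from (seed, station, campaign, sample kind, replicate),
so adding a station or predator never perturbs existing samples.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    Dataset,
    DomainError,
    SampleRecord,
    TaxonRecord,
)
from .selectivity import selectivity_index, station_selectivity
from .taxon_filtering import (
    FilterParams,
    default_exclusion_rules,
    exclude_taxa,
    prevalence_abundance_filter,
)

#: Photoautotroph class labels used for the synthetic prey taxa (cycled
#: if n_taxa exceeds the list).
PREY_CLASSES = (
    "Synechococcales",
    "Bacillariophyceae",
    "Coscinodiscophyceae",
    "Nostocales",
    "Trebouxiophyceae",
    "Prasinophyceae",
    "Cryptophyceae",
    "Eustigmatophyceae",
    "Chrysophyceae",
    "Pedinophyceae",
    "Mediophyceae",
    "Pyramimonadophyceae",
    "Chlorophyceae",
    "Dinophyceae",
    "Pavlovophyceae",
    "Raphidophyceae",
    "Xanthophyceae",
    "Dictyochophyceae",
    "Bolidophyceae",
    "Pelagophyceae",
)

CONTAMINANT_IDS = ("contam_predator", "contam_hetbact", "contam_epibiont")


class SimulationError(ValueError):
    """Raised for inconsistent simulation configurations."""


def _substream(seed: int, *parts: object) -> np.random.Generator:
    """Deterministic per-sample RNG substream keyed by string parts."""
    key = [zlib.crc32(str(p).encode()) for p in parts]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, *key]))


def _geometric_simplex(n: int, ratio: float, offset: int = 0) -> np.ndarray:
    """Strictly positive simplex vector with geometrically decaying weights."""
    v = ratio ** np.arange(n, dtype=float) if ratio != 1.0 else np.ones(n)
    v = np.roll(v, offset)
    return v / v.sum()


def default_alphas(n_taxa: int, predators: Sequence[str]) -> dict[str, np.ndarray]:
    """Per-predator selectivity vectors spanning selective to opportunistic.

    The first predator is strongly concentrated (the selective-feeder
    analogue), the last is uniform (a pure opportunist), intermediates
    decay gently with rotated preference orders so diets differ.
    """
    alphas: dict[str, np.ndarray] = {}
    k = len(predators)
    for i, pred in enumerate(predators):
        if i == k - 1 and k > 1:
            alphas[pred] = _geometric_simplex(n_taxa, 1.0)
        elif i == 0:
            alphas[pred] = _geometric_simplex(n_taxa, 0.35)
        else:
            alphas[pred] = _geometric_simplex(n_taxa, 0.75, offset=3 * i)
    return alphas


def default_water_bases(
    n_taxa: int, stations: Sequence[str]
) -> dict[str, np.ndarray]:
    """Distinct mean water compositions per station (rotated decays)."""
    return {
        st: _geometric_simplex(n_taxa, 0.8, offset=2 * i)
        for i, st in enumerate(stations)
    }


@dataclass
class SimulationConfig:
    """Study design and noise parameters of the synthetic survey.

    Defaults mirror the emulated survey: five gut replicates (pools of five
    individuals) per predator and station, three water replicates, four
    predator species across three stations and two campaigns.  Library
    sizes are in reads; ``contaminant_fractions`` are the expected shares
    of (predator reads, heterotrophic bacteria, epibiont) in a gut sample's
    total, added on top of the prey library.  ``None`` resolves per marker:
    16S gets (0, 0.15, 0.02); 18S gets (0.72, 0, 0.02), the predator share
    matching the crustacean read load the nested-PCR protocol leaves in
    gut samples.
    """

    n_taxa: int = 12
    stations: tuple[str, ...] = ("MS", "SBS", "CBS")
    campaigns: tuple[str, ...] = ("2019-06", "2020-09")
    predators: tuple[str, ...] = ("Temora", "Acartia", "Centropages", "Evadne")
    marker: str = "16S"
    alpha: Mapping[str, np.ndarray] | None = None
    water_base: Mapping[str, np.ndarray] | None = None
    water_concentration: float = 200.0
    gut_library_size: int = 50_000
    water_library_size: int = 50_000
    n_gut_replicates: int = 5
    n_water_replicates: int = 3
    contaminant_fractions: tuple[float, float, float] | None = None
    overdispersion: float | None = None
    seed: int = 0

    def resolved_alpha(self) -> dict[str, np.ndarray]:
        if self.alpha is None:
            return default_alphas(self.n_taxa, self.predators)
        out = {p: np.asarray(a, dtype=float) for p, a in self.alpha.items()}
        for p, a in out.items():
            if len(a) != self.n_taxa or np.any(a < 0):
                raise SimulationError(f"alpha for {p!r} invalid")
            if abs(a.sum() - 1.0) > 1e-9:
                raise SimulationError(f"alpha for {p!r} does not sum to 1")
        missing = [p for p in self.predators if p not in out]
        if missing:
            raise SimulationError(f"alpha missing for predators {missing}")
        return out

    def resolved_water_base(self) -> dict[str, np.ndarray]:
        if self.water_base is None:
            return default_water_bases(self.n_taxa, self.stations)
        out = {s: np.asarray(w, dtype=float) for s, w in self.water_base.items()}
        missing = [s for s in self.stations if s not in out]
        if missing:
            raise SimulationError(f"water_base missing for stations {missing}")
        return out

    def resolved_contaminants(self) -> tuple[float, float, float]:
        if self.contaminant_fractions is None:
            return (0.72, 0.0, 0.02) if self.marker == "18S" else (0.0, 0.15, 0.02)
        f = tuple(float(x) for x in self.contaminant_fractions)
        if any(x < 0 for x in f) or sum(f) >= 1:
            raise SimulationError(
                f"contaminant fractions must be in [0,1) and sum below 1, got {f}"
            )
        return f  # type: ignore[return-value]

    def validate(self) -> "SimulationConfig":
        if self.n_taxa < 2:
            raise SimulationError("need at least 2 prey taxa")
        if self.gut_library_size <= 0 or self.water_library_size <= 0:
            raise SimulationError("library sizes must be positive")
        if self.n_gut_replicates < 1 or self.n_water_replicates < 1:
            raise SimulationError("replicate counts must be >= 1")
        self.resolved_alpha()
        self.resolved_water_base()
        self.resolved_contaminants()
        return self


@dataclass
class GroundTruth:
    """Latent quantities of one simulated survey, for recovery tests."""

    prey_ids: list[str]
    water_compositions: dict[tuple[str, str], pd.Series]
    alpha: dict[str, pd.Series]
    expected_gut: dict[tuple[str, str, str], pd.Series]


def gut_composition(alpha: Sequence[float], w: Sequence[float]) -> np.ndarray:
    """Chesson-mixing diet: p_i proportional to alpha_i * w_i."""
    a = np.asarray(alpha, dtype=float)
    w = np.asarray(w, dtype=float)
    if a.shape != w.shape or a.ndim != 1:
        raise DomainError("alpha and w must be 1-d and aligned")
    if np.any(a < 0) or np.any(w < 0):
        raise DomainError("alpha and w must be non-negative")
    mix = a * w
    total = mix.sum()
    if total <= 0:
        raise SimulationError(
            "predator cannot feed: alpha and w have disjoint support"
        )
    return mix / total


def _prey_taxonomy(n_taxa: int, marker: str) -> dict[str, TaxonRecord]:
    taxonomy = {}
    for i in range(n_taxa):
        cls = PREY_CLASSES[i % len(PREY_CLASSES)]
        label = cls if i < len(PREY_CLASSES) else f"{cls}_{i // len(PREY_CLASSES)}"
        tid = f"prey_{i:03d}"
        domain = "Bacteria" if cls in ("Synechococcales", "Nostocales") else "Eukaryota"
        phylum = "Cyanobacteria" if domain == "Bacteria" else "Ochrophyta"
        lineage = (domain, phylum, label, "", "", "")
        taxonomy[tid] = TaxonRecord(taxon_id=tid, lineage=lineage, marker=marker)
    return taxonomy


def _contaminant_taxonomy(marker: str) -> dict[str, TaxonRecord]:
    lineages = {
        "contam_predator": ("Eukaryota", "Arthropoda", "Crustacea", "Calanoida", "", ""),
        "contam_hetbact": (
            "Bacteria",
            "Proteobacteria",
            "Gammaproteobacteria",
            "",
            "",
            "",
        ),
        "contam_epibiont": ("Eukaryota", "Euglenozoa", "Kinetoplastea", "", "", ""),
    }
    return {
        tid: TaxonRecord(taxon_id=tid, lineage=lin, marker=marker)
        for tid, lin in lineages.items()
    }


def _draw_counts(
    rng: np.random.Generator,
    composition: np.ndarray,
    library: int,
    overdispersion: float | None,
) -> np.ndarray:
    """Multinomial reads, or Dirichlet-multinomial when overdispersed."""
    p = composition
    if overdispersion is not None:
        conc = overdispersion * np.clip(p, 1e-12, None)
        p = rng.dirichlet(conc)
    return rng.multinomial(library, p)


def simulate_dataset(config: SimulationConfig) -> tuple[Dataset, GroundTruth]:
    """Simulate the full survey; deterministic given ``config.seed``.

    Water columns sum exactly to ``water_library_size`` and gut prey reads
    to ``gut_library_size``; contaminant reads are a deterministic top-up
    ``round(library * f / (1 - f_total))`` per class so the expected
    contaminant share of the column total equals the configured fraction.
    """
    config.validate()
    alphas = config.resolved_alpha()
    bases = config.resolved_water_base()
    f_pred, f_het, f_epi = config.resolved_contaminants()
    fractions = dict(
        zip(CONTAMINANT_IDS, (f_pred, f_het, f_epi))
    )
    f_total = f_pred + f_het + f_epi

    prey_tax = _prey_taxonomy(config.n_taxa, config.marker)
    prey_ids = list(prey_tax)
    contam_ids = [cid for cid in CONTAMINANT_IDS if fractions[cid] > 0]
    taxonomy = dict(prey_tax)
    for cid in contam_ids:
        taxonomy[cid] = _contaminant_taxonomy(config.marker)[cid]

    columns: dict[str, np.ndarray] = {}
    metadata: dict[str, SampleRecord] = {}
    water_truth: dict[tuple[str, str], pd.Series] = {}
    expected_gut: dict[tuple[str, str, str], pd.Series] = {}

    n_rows = len(prey_ids) + len(contam_ids)
    for station in config.stations:
        for campaign in config.campaigns:
            rng_w = _substream(config.seed, "water_composition", station, campaign)
            w = rng_w.dirichlet(config.water_concentration * bases[station])
            water_truth[(station, campaign)] = pd.Series(w, index=prey_ids)

            for r in range(1, config.n_water_replicates + 1):
                sid = f"W_{station}_{campaign}_r{r}"
                rng = _substream(config.seed, "water_reads", station, campaign, r)
                reads = _draw_counts(
                    rng, w, config.water_library_size, config.overdispersion
                )
                col = np.zeros(n_rows, dtype=np.int64)
                col[: len(prey_ids)] = reads
                columns[sid] = col
                metadata[sid] = SampleRecord(
                    sample_id=sid,
                    sample_type="water",
                    predator_species="",
                    station=station,
                    campaign=campaign,
                    replicate_id=f"r{r}",
                )

            for predator in config.predators:
                p = gut_composition(alphas[predator], w)
                expected_gut[(predator, station, campaign)] = pd.Series(
                    p, index=prey_ids
                )
                for r in range(1, config.n_gut_replicates + 1):
                    sid = f"G_{predator}_{station}_{campaign}_r{r}"
                    rng = _substream(
                        config.seed, "gut_reads", station, campaign, predator, r
                    )
                    reads = _draw_counts(
                        rng, p, config.gut_library_size, config.overdispersion
                    )
                    col = np.zeros(n_rows, dtype=np.int64)
                    col[: len(prey_ids)] = reads
                    for k, cid in enumerate(contam_ids):
                        f = fractions[cid]
                        extra = int(
                            round(config.gut_library_size * f / (1.0 - f_total))
                        )
                        col[len(prey_ids) + k] = extra
                    columns[sid] = col
                    metadata[sid] = SampleRecord(
                        sample_id=sid,
                        sample_type="gut",
                        predator_species=predator,
                        station=station,
                        campaign=campaign,
                        replicate_id=f"r{r}",
                    )

    counts = pd.DataFrame(
        columns, index=prey_ids + contam_ids, columns=list(columns)
    )
    counts.index.name = "taxon_id"
    dataset = Dataset(
        counts=counts.astype(np.int64), taxonomy=taxonomy, metadata=metadata
    ).validate()
    truth = GroundTruth(
        prey_ids=prey_ids,
        water_compositions=water_truth,
        alpha={p: pd.Series(a, index=prey_ids) for p, a in alphas.items()},
        expected_gut=expected_gut,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# Recovery experiment
# ---------------------------------------------------------------------------


@dataclass
class RecoveryReport:
    """Selectivity-recovery error of the full pipeline on one simulation."""

    per_group: pd.DataFrame  # predator, station, campaign, mean_abs_error
    mean_abs_error: float


def recovery_experiment(
    config: SimulationConfig,
    filter_params: FilterParams = FilterParams(0.0, 0.0),
    noise_free: bool = False,
) -> RecoveryReport:
    """Run simulate -> exclude -> filter -> selectivity and score vs truth.

    For each predator/station/campaign the per-replicate S vectors are
    averaged and compared to the generating ``alpha`` as a mean absolute
    error.  ``noise_free=True`` skips read sampling entirely and scores the
    index on exact compositions (the closed-form inverse: error 0).
    """
    config.validate()
    alphas = config.resolved_alpha()

    rows = []
    if noise_free:
        bases = config.resolved_water_base()
        for station in config.stations:
            for campaign in config.campaigns:
                rng_w = _substream(
                    config.seed, "water_composition", station, campaign
                )
                w = rng_w.dirichlet(config.water_concentration * bases[station])
                for predator in config.predators:
                    p = gut_composition(alphas[predator], w)
                    res = selectivity_index(p, w)
                    err = float(np.mean(np.abs(res.S - alphas[predator])))
                    rows.append(
                        dict(
                            predator=predator,
                            station=station,
                            campaign=campaign,
                            mean_abs_error=err,
                        )
                    )
    else:
        dataset, truth = simulate_dataset(config)
        dataset = exclude_taxa(dataset, default_exclusion_rules())
        for station in config.stations:
            for campaign in config.campaigns:
                for predator in config.predators:
                    retained = prevalence_abundance_filter(
                        dataset, (predator, station, campaign), filter_params
                    )
                    table = station_selectivity(
                        dataset,
                        predator,
                        station,
                        campaign,
                        prey_subset=sorted(retained),
                    )
                    mean_s = (
                        table.dropna(subset=["S"])
                        .groupby("taxon")["S"]
                        .mean()
                    )
                    alpha = truth.alpha[predator]
                    common = [t for t in alpha.index if t in mean_s.index]
                    err = float(
                        np.mean(np.abs(mean_s[common].to_numpy() - alpha[common].to_numpy()))
                    )
                    rows.append(
                        dict(
                            predator=predator,
                            station=station,
                            campaign=campaign,
                            mean_abs_error=err,
                        )
                    )
    per_group = pd.DataFrame(rows)
    return RecoveryReport(
        per_group=per_group,
        mean_abs_error=float(per_group["mean_abs_error"].mean()),
    )
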