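"""End-to-end orchestration of the diet-analysis pipeline.

Stage order is fixed: exclusion -> rank aggregation -> optional
water-station merging (pairwise PERMANOVA on the water communities; station
pairs whose communities cannot be differentiated at ``merge_alpha`` in any
campaign are pooled) -> per-group prevalence/abundance filter -> relative
abundances -> selectivity tables -> diet-overlap matrices and summaries ->
PERMANOVA tables.  Every stage appends to a log; a manifest records the
config hash, seed and output checksums so reruns are verifiable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import diet_overlap, permanova, selectivity
from .data_model import Dataset, load_dataset, write_tables
from .taxon_filtering import (
    ExclusionRule,
    FilterParams,
    RankOverride,
    RankPolicy,
    aggregate_taxa,
    exclude_taxa,
    prevalence_abundance_filter,
    relative_abundance,
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending group."""


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, loadable from one YAML file.

    All analysis choices that the underlying modules leave open (filter
    interpretation, water-replicate aggregation, zero-water handling,
    station-merge threshold, multiplicity correction) are explicit fields
    here with their documented defaults.
    """

    counts_path: str = ""
    taxonomy_path: str = ""
    metadata_path: str = ""
    out_dir: str = "results"
    exclusion_rules: list[ExclusionRule] = field(default_factory=list)
    aggregate: bool = False
    rank_policy: RankPolicy = field(default_factory=RankPolicy)
    filter_params: FilterParams = field(default_factory=FilterParams)
    filter_mode: str = "pooled"
    water_policy: str = "mean_proportions"
    pseudocount: float = 0.0
    merge_stations: bool = False
    merge_alpha: float = 0.05
    n_permutations: int = 999
    correction: str = "BH"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        rules = [
            ExclusionRule(
                rank=r["rank"], pattern=r["pattern"], marker=r.get("marker")
            )
            for r in raw.pop("exclusion_rules", [])
        ]
        rp = raw.pop("rank_policy", None)
        policy = RankPolicy()
        if rp:
            policy = RankPolicy(
                default_rank=rp.get("default_rank", "class"),
                overrides=tuple(
                    RankOverride(
                        match_rank=o["match_rank"],
                        labels=frozenset(o["labels"]),
                        to_rank=o["to_rank"],
                    )
                    for o in rp.get("overrides", [])
                ),
            )
        fp = raw.pop("filter_params", None)
        params = FilterParams(**fp) if fp else FilterParams()
        return cls(
            exclusion_rules=rules, rank_policy=policy, filter_params=params, **raw
        )

    def digest(self) -> str:
        blob = json.dumps(
            {
                k: str(v)
                for k, v in self.__dict__.items()
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    dataset: Dataset
    tables: dict[str, pd.DataFrame]
    written: list[Path]
    manifest: dict[str, Any]
    log: list[str]


def _gut_groups(dataset: Dataset) -> list[tuple[str, str, str]]:
    seen: list[tuple[str, str, str]] = []
    for sid in dataset.sample_ids(sample_type="gut"):
        rec = dataset.metadata[sid]
        key = (rec.predator_species, rec.station, rec.campaign)
        if key not in seen:
            seen.append(key)
    return seen


def merge_indistinct_stations(
    dataset: Dataset,
    merge_alpha: float = 0.05,
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[Dataset, list[str]]:
    """Pool stations whose water communities cannot be differentiated.

    For every campaign, water samples are compared between station pairs by
    pairwise PERMANOVA on Bray-Curtis distances of their relative
    abundances.  A pair is merged only if its adjusted p-value exceeds
    ``merge_alpha`` in every campaign (the communities never separate).
    Merged stations get the joined label ``A+B`` in the returned dataset's
    metadata.  Returns the (possibly relabelled) dataset and a log.
    """
    log: list[str] = []
    water = dataset.sample_ids(sample_type="water")
    stations = sorted({dataset.metadata[s].station for s in water})
    campaigns = sorted({dataset.metadata[s].campaign for s in water})
    if len(stations) < 2:
        return dataset, ["station merge: fewer than 2 stations, nothing to do"]

    keep_separate: set[frozenset[str]] = set()
    tested: set[frozenset[str]] = set()
    for campaign in campaigns:
        samples = dataset.sample_ids(sample_type="water", campaign=campaign)
        labels = [dataset.metadata[s].station for s in samples]
        present = sorted(set(labels))
        if len(present) < 2:
            continue
        comps = relative_abundance(dataset.counts[samples])
        dm = diet_overlap.distance_matrix(comps)
        try:
            pw = permanova.pairwise_permanova(
                dm, labels, n_permutations=n_permutations, seed=seed
            )
        except permanova.PermanovaError as exc:
            log.append(f"station merge: {campaign}: skipped ({exc})")
            continue
        for row in pw:
            pair = frozenset((row.group_a, row.group_b))
            tested.add(pair)
            if row.degenerate:
                continue
            log.append(
                f"station merge: {campaign}: {row.group_a} vs {row.group_b} "
                f"p_adj={row.p_adjusted:.4f}"
            )
            if row.p_adjusted <= merge_alpha:
                keep_separate.add(pair)

    mergeable = [p for p in tested if p not in keep_separate]
    if not mergeable:
        log.append("station merge: all station pairs differentiated; no merge")
        return dataset, log

    # union-find over stations
    parent = {s: s for s in stations}

    def find(s: str) -> str:
        while parent[s] != s:
            s = parent[s]
        return s

    for pair in mergeable:
        a, b = sorted(pair)
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    clusters: dict[str, list[str]] = {}
    for s in stations:
        clusters.setdefault(find(s), []).append(s)
    rename = {}
    for members in clusters.values():
        label = "+".join(sorted(members))
        for s in members:
            rename[s] = label
    merged_names = [l for l in {v for v in rename.values()} if "+" in l]
    log.append(f"station merge: pooled {merged_names} at alpha={merge_alpha}")

    metadata = {
        sid: (
            rec
            if rename.get(rec.station, rec.station) == rec.station
            else type(rec)(
                sample_id=rec.sample_id,
                sample_type=rec.sample_type,
                predator_species=rec.predator_species,
                station=rename[rec.station],
                campaign=rec.campaign,
                replicate_id=rec.replicate_id,
            )
        )
        for sid, rec in dataset.metadata.items()
    }
    out = Dataset(
        counts=dataset.counts.copy(),
        taxonomy=dict(dataset.taxonomy),
        metadata=metadata,
        provenance=list(dataset.provenance) + log,
    )
    return out.validate(), log


def run_pipeline(
    config: PipelineConfig, dataset: Dataset | None = None
) -> PipelineResult:
    """Execute the full analysis; deterministic for a fixed config and seed.

    ``dataset`` may be supplied directly (e.g. fresh from the simulator);
    otherwise it is loaded from the configured paths.
    """
    log: list[str] = []
    tables: dict[str, pd.DataFrame] = {}

    def stage(name: str):
        def wrap(exc: Exception) -> PipelineError:
            return PipelineError(f"stage {name!r} failed: {exc}")

        return wrap

    if dataset is None:
        try:
            dataset = load_dataset(
                config.counts_path, config.taxonomy_path, config.metadata_path
            )
        except Exception as exc:
            raise stage("load")(exc) from exc
    log.append(
        f"load: {len(dataset.taxa)} taxa x {len(dataset.samples)} samples "
        f"(marker {dataset.marker})"
    )

    if config.exclusion_rules:
        try:
            dataset = exclude_taxa(dataset, config.exclusion_rules)
        except Exception as exc:
            raise stage("exclusion")(exc) from exc
        log.append(f"exclusion: {len(dataset.taxa)} taxa remain")

    if config.aggregate:
        try:
            dataset = aggregate_taxa(dataset, config.rank_policy)
        except Exception as exc:
            raise stage("aggregation")(exc) from exc
        log.append(f"aggregation: {len(dataset.taxa)} labels")

    if config.merge_stations:
        try:
            dataset, merge_log = merge_indistinct_stations(
                dataset,
                merge_alpha=config.merge_alpha,
                n_permutations=config.n_permutations,
                seed=config.seed,
            )
        except Exception as exc:
            raise stage("station_merge")(exc) from exc
        log.extend(merge_log)

    groups = _gut_groups(dataset)
    if not groups:
        raise PipelineError("stage 'filter' failed: dataset contains no gut samples")

    retained_rows = []
    retained: dict[tuple[str, str, str], set[str]] = {}
    for grp in groups:
        try:
            keep = prevalence_abundance_filter(
                dataset, grp, config.filter_params, mode=config.filter_mode
            )
        except Exception as exc:
            raise stage("filter")(Exception(f"group {grp}: {exc}")) from exc
        retained[grp] = keep
        for t in sorted(keep):
            retained_rows.append(
                dict(
                    predator=grp[0], station=grp[1], campaign=grp[2], taxon_id=t
                )
            )
        log.append(f"filter: {grp}: {len(keep)} taxa retained")
    tables["retained_taxa"] = pd.DataFrame(retained_rows)

    # compositions of all samples over all remaining taxa (diagnostic output)
    tables["compositions"] = relative_abundance(dataset.counts).rename_axis(
        "taxon_id"
    )

    do_quant = dataset.marker == "16S"
    if not do_quant:
        log.append(
            "selectivity/overlap skipped: quantitative diet statistics use "
            "16S data only"
        )

    if do_quant:
        sel_frames = []
        for predator, station, campaign in groups:
            try:
                sel = selectivity.station_selectivity(
                    dataset,
                    predator,
                    station,
                    campaign,
                    water_policy=config.water_policy,
                    prey_subset=sorted(retained[(predator, station, campaign)]),
                    pseudocount=config.pseudocount,
                )
            except Exception as exc:
                raise stage("selectivity")(
                    Exception(f"group {(predator, station, campaign)}: {exc}")
                ) from exc
            sel_frames.append(sel)
        tables["selectivity"] = pd.concat(sel_frames, ignore_index=True)
        log.append(f"selectivity: {len(tables['selectivity'])} rows")

        predators = sorted({g[0] for g in groups})
        summaries = []
        for predator in predators:
            try:
                summary, dm = diet_overlap.similarity_summary(dataset, predator)
            except diet_overlap.OverlapError as exc:
                log.append(f"overlap: {predator}: skipped ({exc})")
                continue
            sim_pct = (1.0 - dm.d) * 100.0
            frame = pd.DataFrame(
                sim_pct, index=dm.sample_ids, columns=dm.sample_ids
            ).rename_axis("sample_id")
            tables[f"similarity_{predator}"] = frame
            summaries.append(summary.as_frame())
        if summaries:
            tables["overlap_summary"] = pd.concat(summaries, ignore_index=True)

        # PERMANOVA: per predator, do stations differ? plus water by station
        perm_rows = []
        for predator in predators:
            samples = dataset.sample_ids(sample_type="gut", predator=predator)
            labels = [dataset.metadata[s].station for s in samples]
            if len(set(labels)) < 2:
                continue
            comps = relative_abundance(dataset.counts[samples])
            dm = diet_overlap.distance_matrix(comps)
            try:
                res = permanova.permanova_test(
                    dm, labels, config.n_permutations, seed=config.seed
                )
            except permanova.PermanovaError as exc:
                log.append(f"permanova: {predator}: skipped ({exc})")
                continue
            perm_rows.append(
                dict(
                    factor=f"station|gut:{predator}",
                    pseudo_F=res.pseudo_F,
                    R2=res.R2,
                    p_value=res.p_value,
                    n_permutations=res.n_permutations,
                    seed=res.seed,
                )
            )
        water = dataset.sample_ids(sample_type="water")
        wlabels = [dataset.metadata[s].station for s in water]
        if len(set(wlabels)) >= 2:
            comps = relative_abundance(dataset.counts[water])
            dm = diet_overlap.distance_matrix(comps)
            try:
                res = permanova.permanova_test(
                    dm, wlabels, config.n_permutations, seed=config.seed
                )
                perm_rows.append(
                    dict(
                        factor="station|water",
                        pseudo_F=res.pseudo_F,
                        R2=res.R2,
                        p_value=res.p_value,
                        n_permutations=res.n_permutations,
                        seed=res.seed,
                    )
                )
            except permanova.PermanovaError as exc:
                log.append(f"permanova: water: skipped ({exc})")
        if perm_rows:
            tables["permanova"] = pd.DataFrame(perm_rows)

    written = write_tables(tables, config.out_dir)
    checksums = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()[:16] for p in written
    }
    manifest = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_taxa": len(dataset.taxa),
        "n_samples": len(dataset.samples),
        "checksums": checksums,
        "log": log,
    }
    manifest_path = Path(config.out_dir) / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    written.append(manifest_path)
    return PipelineResult(
        dataset=dataset,
        tables=tables,
        written=written,
        manifest=manifest,
        log=log,
    )
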