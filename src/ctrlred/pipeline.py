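"""End-to-end orchestration: simulate -> construct -> metrics -> inference -> reserve.

A declarative YAML config drives the full analysis over a sweep of edge
thresholds, with one seed controlling every source of randomness.  Each stage
emits tidy CSVs; a JSON manifest records the config echo, package version,
seeds and a content hash of every output file, so a rerun with the identical
config and seed reproduces all numeric outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, field_validator
from scipy import stats as sps

from . import __version__ as _pkg_version
from .connectome import (
    Connectome,
    Parcellation,
    binarize,
    group_average_nodal,
    network_means,
    nodal_degree,
    threshold_connectome,
)
from .control import (
    classify_hubs,
    hub_network_distribution,
    nodal_average_controllability,
)
from .errors import ConfigurationError, ParameterError
from .redundancy import count_simple_paths, nodal_redundancy
from .reserve import compare_feature_models, default_feature_sets, fit_breakpoint, residual_adjust
from .stats import (
    assign_age_group,
    group_compare,
    mediate,
    partial_spearman,
    sex_correlation_contrast,
)
from .synthetic import (
    CohortSpec,
    SubjectRecord,
    filter_cohort,
    generate_cohort,
    read_cohort,
    write_cohort,
)

DEFAULT_THRESHOLDS = (0.001, 0.005, 0.010, 0.015)


class RunConfig(BaseModel):
    """Validated, fully defaulted pipeline configuration."""

    model_config = ConfigDict(extra="forbid")

    cohort_dir: str | None = None          # read an existing cohort instead of simulating
    cohort: dict[str, Any] = {}            # CohortSpec overrides for simulation
    thresholds: list[float] = list(DEFAULT_THRESHOLDS)
    path_length: int = 4
    hub_rule: str = "mean_plus_sd"
    hub_parameter: float = 1.0
    age_cut: float = 65.0
    n_boot: int = 10000
    alpha: float = 0.05
    network_family: int | None = None      # default: number of networks
    hub_family: int | None = None          # default: number of hubs found
    reserve_age_filter: float | str = "breakpoint"
    seed: int = 0

    @field_validator("thresholds")
    @classmethod
    def _check_thresholds(cls, v: list[float]) -> list[float]:
        if not v:
            raise ValueError("at least one threshold fraction is required")
        if any(not (0.0 <= f < 1.0) for f in v):
            raise ValueError(f"fractions must lie in [0, 1): {v}")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError(f"fractions must be strictly increasing: {v}")
        return v

    @field_validator("path_length")
    @classmethod
    def _check_length(cls, v: int) -> int:
        if v < 1:
            raise ValueError("path_length must be >= 1")
        return v

    @field_validator("n_boot")
    @classmethod
    def _check_boot(cls, v: int) -> int:
        if v < 1:
            raise ValueError("n_boot must be >= 1")
        return v

    def cohort_spec(self) -> CohortSpec:
        kwargs = dict(self.cohort)
        kwargs.setdefault("seed", self.seed)
        try:
            return CohortSpec(**kwargs)
        except TypeError as exc:  # unknown CohortSpec key
            raise ConfigurationError(str(exc)) from exc


def validate_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML config; an empty file yields pure defaults."""
    data: dict[str, Any] = {}
    if path is not None:
        raw = Path(path).read_text()
        loaded = yaml.safe_load(raw)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        data = loaded
    try:
        return RunConfig(**data)
    except (ValueError, TypeError) as exc:
        raise ConfigurationError(str(exc)) from exc


# ---------------------------------------------------------------------------
# Metric table construction


def subject_network_table(
    records: list[SubjectRecord],
    connectomes: list[Connectome],
    threshold: float,
    path_length: int = 4,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Join phenotypes to per-network metric means at one threshold.

    Returns the cohort table (columns ``ac_<net>``, ``deg_<net>``,
    ``red_<net>`` per network plus ``total_edges``) and the stacked per-node
    metric matrices used for group-level nodal analyses.
    """
    parc = connectomes[0].parcellation
    nets = parc.networks
    rows = []
    nodal = {"average_controllability": [], "degree": [], "redundancy": []}
    for rec, con in zip(records, connectomes):
        thr = threshold_connectome(con, threshold)
        binr = binarize(thr)
        ac = nodal_average_controllability(thr)
        deg = nodal_degree(binr)
        red = nodal_redundancy(
            count_simple_paths(binr, path_length, keep_per_length=False),
            subject_id=con.subject_id, threshold_fraction=threshold,
        )
        nodal["average_controllability"].append(ac.values)
        nodal["degree"].append(deg.values)
        nodal["redundancy"].append(red.values)
        row: dict[str, Any] = dataclasses.asdict(rec)
        row["total_edges"] = thr.edge_count()
        for prefix, metric in (("ac", ac), ("deg", deg), ("red", red)):
            means = network_means(metric, parc).means
            for net in nets:
                row[f"{prefix}_{net}"] = means[net]
        rows.append(row)
    table = pd.DataFrame(rows)
    table["age_group"] = assign_age_group(table["age"])
    stacks = {k: np.vstack(v) for k, v in nodal.items()}
    return table, stacks


# ---------------------------------------------------------------------------
# Analysis stages


def age_metric_correlations(table: pd.DataFrame, nets: tuple[str, ...],
                            family: int) -> pd.DataFrame:
    """Education-adjusted Spearman correlations of age with each network metric."""
    rows = []
    for prefix, metric in (("ac", "average_controllability"),
                           ("deg", "degree"), ("red", "redundancy")):
        for net in nets:
            r = partial_spearman(
                table["age"], table[f"{prefix}_{net}"],
                covariates=table[["education_years"]].to_numpy(),
                family_size=family, covariate_names=("education_years",),
            )
            rows.append({
                "x": "age", "metric": metric, "network": net, "rho": r.rho,
                "p_raw": r.p_raw, "p_adjusted": r.p_adjusted, "n": r.n,
                "family_size": family,
            })
    return pd.DataFrame(rows)


def speed_metric_correlations(table: pd.DataFrame, nets: tuple[str, ...],
                              family: int) -> pd.DataFrame:
    """Education-adjusted Spearman correlations of processing speed with metrics."""
    rows = []
    for prefix, metric in (("ac", "average_controllability"),
                           ("red", "redundancy")):
        for net in nets:
            r = partial_spearman(
                table["processing_speed"], table[f"{prefix}_{net}"],
                covariates=table[["education_years"]].to_numpy(),
                family_size=family, covariate_names=("education_years",),
            )
            rows.append({
                "x": "processing_speed", "metric": metric, "network": net,
                "rho": r.rho, "p_raw": r.p_raw, "p_adjusted": r.p_adjusted,
                "n": r.n, "family_size": family,
            })
    return pd.DataFrame(rows)


def sex_contrasts(table: pd.DataFrame, nets: tuple[str, ...],
                  family: int) -> pd.DataFrame:
    """Fisher z contrasts of sex-specific age-controllability correlations."""
    rows = []
    for net in nets:
        parts = {}
        for sex in ("F", "M"):
            sub = table[table["sex"] == sex]
            rho, _ = sps.spearmanr(sub["age"], sub[f"ac_{net}"])
            parts[sex] = (float(rho), len(sub))
        z, p = sex_correlation_contrast(parts["F"][0], parts["F"][1],
                                        parts["M"][0], parts["M"][1])
        rows.append({
            "network": net, "rho_f": parts["F"][0], "n_f": parts["F"][1],
            "rho_m": parts["M"][0], "n_m": parts["M"][1], "z": z,
            "p_raw": p, "p_adjusted": min(1.0, p * family),
        })
    return pd.DataFrame(rows)


def network_mediations(table: pd.DataFrame, nets: tuple[str, ...],
                       family: int, n_boot: int, alpha: float,
                       seed: int) -> pd.DataFrame:
    """Parallel mediations of the age -> controllability path per network.

    Degree is tested as the mediator with education as covariate; redundancy
    is tested with education plus rank-transformed degree as covariates,
    isolating the multi-step-path contribution beyond first-order edges.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=2 * len(nets))
    rows = []
    edu = table["education_years"].to_numpy(dtype=float)
    for i, net in enumerate(nets):
        age = table["age"].to_numpy(dtype=float)
        ac = table[f"ac_{net}"].to_numpy(dtype=float)
        deg = table[f"deg_{net}"].to_numpy(dtype=float)
        red = table[f"red_{net}"].to_numpy(dtype=float)
        res_deg = mediate(
            age, deg, ac, covariates=edu[:, None], n_boot=n_boot, alpha=alpha,
            family_size=family, seed=int(seeds[2 * i]),
            covariate_names=("education_years",),
        )
        ranked_deg = sps.rankdata(deg)
        res_red = mediate(
            age, red, ac, covariates=np.column_stack([edu, ranked_deg]),
            n_boot=n_boot, alpha=alpha, family_size=family,
            seed=int(seeds[2 * i + 1]),
            covariate_names=("education_years", "ranked_degree"),
        )
        for mediator, res in (("degree", res_deg), ("redundancy", res_red)):
            rows.append({
                "network": net, "mediator": mediator, "a": res.a, "b": res.b,
                "c_total": res.c_total, "c_prime": res.c_prime,
                "indirect": res.indirect, "ci_lower": res.ci_lower,
                "ci_upper": res.ci_upper, "conf_level": res.conf_level,
                "n_boot": res.n_boot, "significant": res.significant,
                "n": res.n,
            })
    return pd.DataFrame(rows)


def hub_analysis(table: pd.DataFrame, stacks: dict[str, np.ndarray],
                 parc: Parcellation, config: RunConfig) -> dict[str, Any]:
    """Classify control hubs in middle-aged subjects and contrast age groups."""
    middle = (table["age_group"] == "middle").to_numpy()
    from .connectome import NodalMetrics

    group_ac = NodalMetrics(
        "group-middle", "average_controllability",
        stacks["average_controllability"][middle].mean(axis=0),
    )
    hubs = classify_hubs(group_ac, parc, rule=config.hub_rule,
                         parameter=config.hub_parameter)
    dist = hub_network_distribution(hubs, parc)
    family = config.hub_family or len(hubs.hub_indices)
    rows = []
    for idx, pid in zip(hubs.hub_indices, hubs.hub_ids):
        vals = stacks["average_controllability"][:, idx]
        welch = group_compare(vals, table["age_group"], method="welch_anova",
                              family_size=family)
        ancova = group_compare(
            vals, table["age_group"],
            covariates=table[["education_years"]].astype(float),
            method="ancova", family_size=family,
        )
        rows.append({
            "parcel_id": pid, "network": parc.labels[idx],
            "group_ac": float(group_ac.values[idx]),
            "welch_F": welch.F, "welch_p_adjusted": welch.p_adjusted,
            "ancova_F": ancova.F, "ancova_p_adjusted": ancova.p_adjusted,
            "family_size": family,
        })
    nodal_corr = _nodal_associations(stacks)
    return {
        "hubs": hubs, "distribution": dist,
        "comparisons": pd.DataFrame(rows), "nodal_associations": nodal_corr,
    }


def _nodal_associations(stacks: dict[str, np.ndarray]) -> pd.DataFrame:
    """Group-level nodal degree/redundancy vs controllability rank correlations."""
    from .stats import residualize_on

    deg = stacks["degree"].mean(axis=0)
    red = stacks["redundancy"].mean(axis=0)
    ac = stacks["average_controllability"].mean(axis=0)
    rows = []
    for name, x in (("degree", deg), ("redundancy", red)):
        rho, p = sps.spearmanr(x, ac)
        rows.append({"x": name, "y": "average_controllability",
                     "rho": float(rho), "p": float(p), "degree_regressed": False})
    rho, p = sps.spearmanr(residualize_on(red, deg), residualize_on(ac, deg))
    rows.append({"x": "redundancy", "y": "average_controllability",
                 "rho": float(rho), "p": float(p), "degree_regressed": True})
    return pd.DataFrame(rows)


def reserve_stage(table: pd.DataFrame, nets: tuple[str, ...],
                  config: RunConfig) -> dict[str, Any]:
    """Breakpoint fits, residual-method reserve test, and GLM comparison."""
    fits = {
        comp: fit_breakpoint(table["age"], table[f"{comp}_volume"])
        for comp in ("hippocampal", "subcortical", "cortical")
    }
    if config.reserve_age_filter == "breakpoint":
        age_min = fits["hippocampal"].breakpoint_age
    else:
        age_min = float(config.reserve_age_filter)

    work = table.copy()
    for comp in ("hippocampal", "subcortical", "cortical"):
        work[f"{comp}_adj"] = residual_adjust(
            work[f"{comp}_volume"], work["intracranial_volume"]
        )
    older = work[work["age"] > age_min]
    r, p = sps.pearsonr(older["hippocampal_adj"], older["processing_speed"])
    feature_sets = default_feature_sets(
        gm=[f"{c}_adj" for c in ("hippocampal", "subcortical", "cortical")],
        control=[f"ac_{net}" for net in nets],
        redundancy=[f"red_{net}" for net in nets],
    )
    comparison = compare_feature_models(
        work, outcome="processing_speed", feature_sets=feature_sets,
        age_min=age_min,
    )
    return {
        "breakpoints": fits, "age_min": float(age_min),
        "older_n": int(len(older)),
        "hippocampal_speed_r": float(r), "hippocampal_speed_p": float(p),
        "model_comparison": comparison,
    }


# ---------------------------------------------------------------------------
# Full run


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict[str, Any]:
    """Execute every stage for every threshold and write the report bundle.

    Returns the manifest (also written to ``manifest.json``): config echo,
    package version, per-file content hashes and per-stage wall times.  Any
    stage failure aborts with the stage name recorded.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package_version": _pkg_version,
        "config": json.loads(config.model_dump_json()),
        "seed": config.seed,
        "stages": {},
        "hashes": {},
    }
    stage_times: dict[str, float] = {}

    def finish_stage(name: str, t0: float, files: list[Path]) -> None:
        stage_times[name] = round(time.time() - t0, 3)
        rels = [str(f.relative_to(out)) for f in files]
        manifest["stages"][name] = rels
        for f, rel in zip(files, rels):
            manifest["hashes"][rel] = _sha256(f)

    current_stage = "simulate"
    try:
        t0 = time.time()
        if config.cohort_dir is not None:
            records, connectomes = read_cohort(config.cohort_dir)
            spec = None
        else:
            spec = config.cohort_spec()
            records, connectomes = generate_cohort(spec)
        cohort_out = out / "cohort"
        write_cohort(records, connectomes, cohort_out, spec=spec)
        finish_stage("simulate", t0,
                     sorted(cohort_out.rglob("*.csv"))
                     + sorted(cohort_out.rglob("*.tsv")))

        current_stage = "filter"
        t0 = time.time()
        n_before = len(records)
        kept = filter_cohort(records)
        kept_ids = {r.subject_id for r in kept}
        connectomes = [c for c in connectomes if c.subject_id in kept_ids]
        records = kept
        manifest["n_subjects_before_filter"] = n_before
        manifest["n_subjects_after_filter"] = len(records)
        finish_stage("filter", t0, [])

        parc = connectomes[0].parcellation
        nets = parc.networks
        family = config.network_family or len(nets)
        rng = np.random.default_rng(config.seed)
        med_seeds = rng.integers(0, 2**31 - 1, size=len(config.thresholds))

        robustness_rows = []
        edge_counts: dict[str, list[int]] = {}
        primary_outputs: dict[str, Any] = {}
        for ti, frac in enumerate(config.thresholds):
            current_stage = f"threshold_{frac}"
            t0 = time.time()
            tag = f"{frac:g}"
            table, stacks = subject_network_table(
                records, connectomes, frac, config.path_length
            )
            for sid, cnt in zip(table["subject_id"], table["total_edges"]):
                edge_counts.setdefault(sid, []).append(int(cnt))
            files = []
            p = out / f"cohort_table_thr{tag}.csv"
            table.to_csv(p, index=False); files.append(p)
            age_corr = age_metric_correlations(table, nets, family)
            p = out / f"age_correlations_thr{tag}.csv"
            age_corr.to_csv(p, index=False); files.append(p)
            speed_corr = speed_metric_correlations(table, nets, family)
            p = out / f"speed_correlations_thr{tag}.csv"
            speed_corr.to_csv(p, index=False); files.append(p)
            med = network_mediations(table, nets, family, config.n_boot,
                                     config.alpha, int(med_seeds[ti]))
            p = out / f"mediations_thr{tag}.csv"
            med.to_csv(p, index=False); files.append(p)
            sx = sex_contrasts(table, nets, family)
            p = out / f"sex_contrasts_thr{tag}.csv"
            sx.to_csv(p, index=False); files.append(p)
            for _, row in age_corr.iterrows():
                robustness_rows.append({
                    "threshold": frac, "metric": row["metric"],
                    "network": row["network"], "rho": row["rho"],
                    "p_adjusted": row["p_adjusted"],
                    "significant": row["p_adjusted"] < 0.05,
                })
            if ti == 0:
                primary_outputs = {"table": table, "stacks": stacks}
            finish_stage(f"threshold_{tag}", t0, files)

        current_stage = "hubs"
        t0 = time.time()
        hub_out = hub_analysis(primary_outputs["table"],
                               primary_outputs["stacks"], parc, config)
        files = []
        p = out / "hub_comparisons.csv"
        hub_out["comparisons"].to_csv(p, index=False); files.append(p)
        p = out / "hub_distribution.csv"
        hub_out["distribution"].rename_axis("network").reset_index().to_csv(
            p, index=False); files.append(p)
        p = out / "nodal_associations.csv"
        hub_out["nodal_associations"].to_csv(p, index=False); files.append(p)
        p = out / "hubs.json"
        p.write_text(json.dumps({
            "rule": hub_out["hubs"].rule, "parameter": hub_out["hubs"].parameter,
            "hub_ids": list(hub_out["hubs"].hub_ids),
            "values": list(hub_out["hubs"].values),
        }, indent=2)); files.append(p)
        finish_stage("hubs", t0, files)

        current_stage = "reserve"
        t0 = time.time()
        res = reserve_stage(primary_outputs["table"], nets, config)
        files = []
        p = out / "model_comparison.csv"
        res["model_comparison"].table.to_csv(p, index=False); files.append(p)
        p = out / "breakpoints.json"
        p.write_text(json.dumps({
            comp: {
                "breakpoint_age": fit.breakpoint_age,
                "segment_slopes": list(fit.segment_slopes),
                "segment_stats": [list(s) for s in fit.segment_stats],
            }
            for comp, fit in res["breakpoints"].items()
        } | {
            "age_min_used": res["age_min"], "older_n": res["older_n"],
            "hippocampal_speed_r": res["hippocampal_speed_r"],
            "hippocampal_speed_p": res["hippocampal_speed_p"],
        }, indent=2)); files.append(p)
        finish_stage("reserve", t0, files)

        current_stage = "robustness"
        t0 = time.time()
        rob = pd.DataFrame(robustness_rows)
        persist = (
            rob.groupby(["metric", "network"])["significant"].all()
            .rename("significant_all_thresholds").reset_index()
        )
        mono = all(
            all(b <= a for a, b in zip(v, v[1:])) for v in edge_counts.values()
        )
        files = []
        p = out / "robustness_long.csv"
        rob.to_csv(p, index=False); files.append(p)
        p = out / "robustness_summary.csv"
        persist.to_csv(p, index=False); files.append(p)
        manifest["edge_counts_monotone_across_thresholds"] = bool(mono)
        finish_stage("robustness", t0, files)
    except Exception:
        manifest["failed_stage"] = current_stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    manifest["stage_seconds"] = stage_times
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
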