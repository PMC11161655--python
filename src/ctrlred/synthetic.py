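"""Seeded synthetic cohorts of connectomes and phenotypes.

The generator emulates the statistical structure of a cross-sectional aging
connectome study: n subjects aged 40-90 with weighted symmetric streamline
matrices, age-dependent edge loss concentrated in designated large-scale
networks (producing simultaneous declines in degree, redundancy and average
controllability there), processing speed linearly coupled to network metrics
and grey-matter volume plus Gaussian noise, and grey-matter volumes following
two-segment linear age trajectories with a breakpoint near age 67.

It emulates the *structure* downstream stages assume, not the marginal
distributions of any real dataset; there is no simulation of diffusion MRI,
tractography or imaging artifacts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .connectome import (
    Connectome,
    NodalMetrics,
    Parcellation,
    binarize,
    make_block_parcellation,
    network_means,
    read_connectome,
    threshold_connectome,
    write_connectome,
)
from .control import nodal_average_controllability
from .errors import ParameterError, ValidationError
from .redundancy import count_simple_paths, nodal_redundancy
from .stats import residualize_on

#: Female share observed in the emulated cohort (281 of 480 subjects).
FEMALE_FRACTION = 281 / 480


def _default_speed_coupling() -> dict[str, float]:
    return {"average_controllability": 2.0, "redundancy": 2.0, "gm_volume": 2.0}


def _default_gm_slopes() -> dict[str, tuple[float, float]]:
    # (pre-breakpoint, post-breakpoint) slope in mm^3 per year
    return {
        "hippocampal": (3.0, -45.0),
        "subcortical": (40.0, -400.0),
        "cortical": (-800.0, -2500.0),
    }


@dataclass
class CohortSpec:
    """All knobs of the synthetic cohort, plus the seed.

    ``decline_rate`` is the per-year slope of the Bernoulli edge-deletion
    probability applied to edges inside ``age_decline_networks`` (edges with
    one endpoint inside decline at ``between_network_decline`` times the
    rate).  The default of 0.005/yr was calibrated by Monte Carlo so that at
    the default cohort size each designated network shows per-network
    Spearman correlations of roughly -0.25 between age and mean average
    controllability and roughly -0.5 between age and mean degree, the
    magnitudes the downstream inference stages are built to detect.
    """

    n_subjects: int = 480
    age_range: tuple[float, float] = (40.0, 90.0)
    n_parcels: int = 100
    n_networks: int = 17
    parcel_to_network: Mapping[str, str] | None = None
    baseline_density: float = 0.2
    edge_weight_scale: float = 50.0
    weight_sigma: float = 0.8
    hub_heterogeneity: float = 0.4
    age_decline_networks: tuple[str, ...] = ("DefaultB", "ContB", "LimbicB")
    decline_rate: float = 0.005
    between_network_decline: float = 0.5
    speed_coupling: Mapping[str, float] = field(default_factory=_default_speed_coupling)
    speed_intercept: float = 50.0
    noise_sd: float = 5.0
    gm_breakpoint_age: float = 67.0
    gm_slopes: Mapping[str, tuple[float, float]] = field(default_factory=_default_gm_slopes)
    sex_offset: float = 0.0
    threshold_fraction: float = 0.001
    path_length: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ParameterError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if not (0.0 < self.baseline_density < 1.0):
            raise ParameterError(
                f"baseline_density must be in (0, 1), got {self.baseline_density}"
            )
        lo, hi = self.age_range
        if not (lo < hi):
            raise ParameterError("age_range must satisfy min < max")
        if self.n_parcels < self.n_networks or self.n_networks < 1:
            raise ParameterError("need n_parcels >= n_networks >= 1")
        if self.edge_weight_scale <= 0 or self.noise_sd <= 0:
            raise ParameterError("edge_weight_scale and noise_sd must be positive")
        if self.decline_rate < 0:
            raise ParameterError("decline_rate must be >= 0")

    def parcellation(self) -> Parcellation:
        if self.parcel_to_network is not None:
            ids = tuple(self.parcel_to_network)
            return Parcellation(ids, tuple(self.parcel_to_network[i] for i in ids))
        return make_block_parcellation(self.n_parcels, self.n_networks)


@dataclass
class SubjectRecord:
    """Per-subject phenotypes (demographics, cognition, grey-matter volumes)."""

    subject_id: str
    age: float
    sex: str
    education_years: int
    moca: float
    processing_speed: float
    flexibility: float
    executive: float
    vocabulary: float
    hippocampal_volume: float
    subcortical_volume: float
    cortical_volume: float
    intracranial_volume: float


def _piecewise_trend(age: np.ndarray, lo: float, bp: float,
                     slopes: tuple[float, float]) -> np.ndarray:
    pre, post = slopes
    return pre * (np.minimum(age, bp) - lo) + post * np.maximum(age - bp, 0.0)


def generate_cohort(spec: CohortSpec) -> tuple[list[SubjectRecord], list[Connectome]]:
    """Generate one seeded cohort: phenotype records plus one connectome each.

    Identical specs (including seed) yield bit-identical cohorts.
    """
    rng = np.random.default_rng(spec.seed)
    parc = spec.parcellation()
    n, npar = spec.n_subjects, parc.n_parcels
    lo, hi = spec.age_range

    ages = rng.uniform(lo, hi, n)
    sexes = np.where(rng.random(n) < FEMALE_FRACTION, "F", "M")
    education = rng.integers(8, 23, n)
    moca = np.clip(np.rint(rng.normal(27.0, 2.0, n)), 0, 30)
    flexibility = rng.normal(100.0, 15.0, n)
    executive = rng.normal(100.0, 15.0, n)
    vocabulary = rng.normal(100.0, 15.0, n)

    icv = rng.normal(1.5e6, 1.3e5, n)
    trends = {
        comp: _piecewise_trend(ages, lo, spec.gm_breakpoint_age, tuple(slopes))
        for comp, slopes in spec.gm_slopes.items()
    }
    hippocampal = 7500.0 + 0.004 * (icv - 1.5e6) + trends["hippocampal"] \
        + rng.normal(0.0, 250.0, n)
    subcortical = 6.0e4 + 0.03 * (icv - 1.5e6) + trends["subcortical"] \
        + rng.normal(0.0, 2000.0, n)
    cortical = 5.0e5 + 0.25 * (icv - 1.5e6) + trends["cortical"] \
        + rng.normal(0.0, 1.5e4, n)

    # shared node propensities give a stable hub structure across subjects
    u = rng.lognormal(0.0, spec.hub_heterogeneity, npar)
    base_p = np.clip(spec.baseline_density * np.outer(u, u), 0.0, 0.95)
    labels = np.asarray(parc.labels)
    in_decline = np.isin(labels, spec.age_decline_networks).astype(float)
    # 1 when both endpoints inside a decline network, between_network_decline
    # when one endpoint is, 0 otherwise
    decline_w = np.add.outer(in_decline, in_decline) / 2.0
    decline_w = np.where(decline_w == 0.5, spec.between_network_decline,
                         np.minimum(decline_w, 1.0))

    iu = np.triu_indices(npar, k=1)
    connectomes: list[Connectome] = []
    log_scale = np.log(spec.edge_weight_scale)
    for i in range(n):
        p = base_p if sexes[i] == "F" else np.clip(
            base_p * (1.0 + spec.sex_offset), 0.0, 0.95)
        present = rng.random(len(iu[0])) < p[iu]
        del_p = np.clip(
            spec.decline_rate * (ages[i] - lo) * decline_w[iu], 0.0, 1.0)
        keep = present & (rng.random(len(iu[0])) >= del_p)
        wts = np.rint(np.exp(rng.normal(log_scale, spec.weight_sigma,
                                        len(iu[0]))))
        wts = np.maximum(wts, 1.0) * keep
        W = np.zeros((npar, npar))
        W[iu] = wts
        W += W.T
        connectomes.append(
            Connectome(W, parc, subject_id=f"sub-{i + 1:04d}")
        )

    speed = np.full(n, spec.speed_intercept)
    coupling = dict(spec.speed_coupling)
    net_couplings = {k: v for k, v in coupling.items() if k != "gm_volume"}
    if net_couplings:
        channels: dict[str, np.ndarray] = {k: np.empty(n) for k in net_couplings}
        for i, c in enumerate(connectomes):
            thr = threshold_connectome(c, spec.threshold_fraction)
            binr = binarize(thr)
            for metric in net_couplings:
                if metric == "average_controllability":
                    nm = nodal_average_controllability(thr)
                elif metric == "redundancy":
                    nm = nodal_redundancy(
                        count_simple_paths(binr, spec.path_length,
                                           keep_per_length=False),
                        subject_id=c.subject_id)
                elif metric == "degree":
                    nm = NodalMetrics(c.subject_id, "degree",
                                      binr.weights.sum(axis=1))
                else:
                    raise ParameterError(f"unknown speed channel {metric!r}")
                summ = network_means(nm, parc)
                channels[metric][i] = summ.means[
                    list(spec.age_decline_networks)].mean()
        for metric, coef in net_couplings.items():
            z = (channels[metric] - channels[metric].mean())
            sd = z.std(ddof=0)
            if sd > 0:
                speed = speed + coef * z / sd
    if "gm_volume" in coupling:
        adj = residualize_on(hippocampal, icv)
        sd = adj.std(ddof=0)
        if sd > 0:
            speed = speed + coupling["gm_volume"] * adj / sd
    speed = speed + rng.normal(0.0, spec.noise_sd, n)

    records = [
        SubjectRecord(
            subject_id=f"sub-{i + 1:04d}", age=float(ages[i]),
            sex=str(sexes[i]), education_years=int(education[i]),
            moca=float(moca[i]), processing_speed=float(speed[i]),
            flexibility=float(flexibility[i]), executive=float(executive[i]),
            vocabulary=float(vocabulary[i]),
            hippocampal_volume=float(hippocampal[i]),
            subcortical_volume=float(subcortical[i]),
            cortical_volume=float(cortical[i]),
            intracranial_volume=float(icv[i]),
        )
        for i in range(n)
    ]
    return records, connectomes


_SCORE_FIELDS = ("flexibility", "executive", "vocabulary")


def filter_cohort(records: Sequence[SubjectRecord]) -> list[SubjectRecord]:
    """Apply the cognitive-health inclusion rules of the emulated study.

    Subjects older than 65 with MoCA below 23/30 are excluded, as are
    subjects aged 65-90 whose cognitive flexibility, executive or vocabulary
    score falls more than two standard deviations below the cohort mean.
    Younger subjects are retained regardless of those scores.  The 2-SD rule
    is iterated to a fixed point (cohort statistics recomputed after each
    exclusion pass) so that filtering is exactly idempotent.
    """
    if not records:
        raise ValidationError("empty cohort")
    for r in records:
        for f in ("moca", *_SCORE_FIELDS):
            v = getattr(r, f, None)
            if v is None or not np.isfinite(v):
                raise ValidationError(
                    f"subject {r.subject_id}: missing cognitive field {f}"
                )
    kept = [r for r in records if not (r.age > 65.0 and r.moca < 23.0)]
    while True:
        stats = {
            f: (np.mean([getattr(r, f) for r in kept]),
                np.std([getattr(r, f) for r in kept], ddof=1))
            for f in _SCORE_FIELDS
        }
        def poor(r: SubjectRecord) -> bool:
            if not (65.0 <= r.age <= 90.0):
                return False
            return any(
                getattr(r, f) < stats[f][0] - 2.0 * stats[f][1]
                for f in _SCORE_FIELDS
            )
        nxt = [r for r in kept if not poor(r)]
        if len(nxt) == len(kept):
            return nxt
        kept = nxt


# ---------------------------------------------------------------------------
# Cohort I/O


def write_cohort(records: Sequence[SubjectRecord],
                 connectomes: Sequence[Connectome],
                 out_dir: str | Path,
                 spec: CohortSpec | None = None) -> None:
    """Write phenotypes (CSV), parcellation (TSV), adjacencies (TSV) and spec (JSON)."""
    out = Path(out_dir)
    (out / "connectomes").mkdir(parents=True, exist_ok=True)
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
        out / "phenotypes.csv", index=False,
        float_format=lambda v: repr(float(v)),  # shortest exact round trip
    )
    parc = connectomes[0].parcellation
    parc.to_tsv(out / "parcellation.tsv")
    for c in connectomes:
        write_connectome(c, out / "connectomes" / f"{c.subject_id}.tsv")
    if spec is not None:
        payload = dataclasses.asdict(spec)
        payload["parcel_to_network"] = (
            dict(spec.parcel_to_network) if spec.parcel_to_network else None
        )
        (out / "cohort_spec.json").write_text(json.dumps(payload, indent=2))


def read_cohort(in_dir: str | Path) -> tuple[list[SubjectRecord], list[Connectome]]:
    """Read a cohort previously written by :func:`write_cohort`."""
    src = Path(in_dir)
    parc = Parcellation.from_tsv(src / "parcellation.tsv")
    df = pd.read_csv(src / "phenotypes.csv", float_precision="round_trip")
    records = [SubjectRecord(**row) for row in df.to_dict("records")]
    connectomes = [
        read_connectome(src / "connectomes" / f"{r.subject_id}.tsv", parc,
                        subject_id=r.subject_id)
        for r in records
    ]
    return records, connectomes
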