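"""End-to-end study orchestration.

Runs the full within-subject gradient pipeline on a synthetic study:
simulate scans -> nuisance regression and band-pass -> Pearson connectome
-> group template (average, Fisher z, top-fraction threshold) -> cosine
affinity -> diffusion embedding -> Procrustes alignment of individual
gradients -> network dispersion -> repeated-measures statistics with the
frame-wise-displacement covariate, Bonferroni correction, and (for retest
designs) ANOVA and ReML intraclass correlations.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import conditioning, connectome, dispersion, embedding, reliability, synthetic
from .networks import NETWORKS

__all__ = ["StudyConfig", "StudyResult", "run_group_template", "run_full_study"]

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """Complete configuration of a synthetic study run.

    Every decision the pipeline depends on is surfaced here (nothing is
    hard-coded downstream): generator sizes and effect magnitudes, the
    band-pass edges, the sparsification fraction, the diffusion-operator
    parameters, the dispersion dimensionality and aggregator, and the
    alpha level with its Bonferroni family size.
    """

    # study design
    n_subjects: int = 21
    n_nodes: int = 280
    g_dims: int = 2
    n_timepoints: int = 240
    interval: float = 2.0
    sites: tuple[str, ...] = ("site1",)
    retest: bool = False
    # planted geometry and effects
    network_spread: float = 0.4
    noise_sd: float = 1.0
    ec_spread_multipliers: dict = field(
        default_factory=lambda: {"VN": 0.85, "SMN": 0.85}
    )
    ec_outward_shifts: dict = field(default_factory=lambda: {"FPN": 0.3})
    subject_spread_sd: float = 0.1
    retest_between_sd: float = 0.1
    retest_within_sd: float = 0.12247448713915891  # planted ICC = 0.4
    # confounds
    fd_mean_ec: float = 0.053
    fd_mean_eo: float = 0.044
    confound_leak_sd: float = 0.2
    # conditioning
    bandpass_low_hz: float = 0.01
    bandpass_high_hz: float = 0.1
    # connectome / embedding
    threshold_fraction: float = 0.1
    embedding_alpha: float = 0.5
    diffusion_time: float = 0.0
    n_components: int = 5
    # dispersion
    dims: int = 2
    aggregator: str = "sum"
    # inference
    alpha_level: float = 0.05
    family_size: int = 14
    seed: int = 0

    def __post_init__(self) -> None:
        self.sites = tuple(self.sites)
        self.ec_spread_multipliers = {
            str(k): float(v) for k, v in self.ec_spread_multipliers.items()
        }
        self.ec_outward_shifts = {
            str(k): float(v) for k, v in self.ec_outward_shifts.items()
        }

    def save(self, path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"
        )

    @classmethod
    def load(cls, path) -> "StudyConfig":
        return cls(**json.loads(Path(path).read_text()))

    @property
    def n_sessions(self) -> int:
        return 2 if self.retest else 1

    def design(self) -> synthetic.StudyDesign:
        return synthetic.StudyDesign(
            n_subjects=self.n_subjects,
            sites=self.sites,
            n_sessions=self.n_sessions,
            n_timepoints=self.n_timepoints,
            interval=self.interval,
            retest=self.retest,
            seed=self.seed,
        )


@dataclass
class ScanRecord:
    """One simulated scan after conditioning: metadata, Pearson matrix and
    the scan's mean frame-wise displacement."""

    subject: str
    site: str
    condition: str
    session: str
    matrix: connectome.ConnectivityMatrix
    mean_fd: float


@dataclass
class StudyResult:
    """Everything a full study run produces."""

    config: StudyConfig
    template: embedding.GradientEmbedding
    dispersion: pd.DataFrame
    comparisons: pd.DataFrame
    fd_test: reliability.RmAnovaResult
    icc: pd.DataFrame | None
    icc_comparisons: pd.DataFrame | None
    labels: np.ndarray


def _condition_effect(config: StudyConfig, geom: synthetic.LatentGeometry) -> synthetic.ConditionEffect:
    grand = geom.centroids.mean(axis=0)
    shifts = {}
    for name, magnitude in config.ec_outward_shifts.items():
        c = geom.centroids[NETWORKS.index(name)]
        direction = c - grand
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm else np.eye(geom.n_dims)[0]
        shifts[name] = magnitude * direction
    return synthetic.ConditionEffect(
        spread_multipliers=dict(config.ec_spread_multipliers),
        centroid_shifts=shifts,
    )


def _generate_scans(config: StudyConfig) -> tuple[list[ScanRecord], synthetic.LatentGeometry]:
    """Simulate and condition every scan of the study; returns Pearson
    matrices plus the base geometry (whose labels drive dispersion)."""
    t0 = time.perf_counter()
    design = config.design()
    ss = np.random.SeedSequence(config.seed)
    master = np.random.default_rng(ss.spawn(1)[0])
    geom = synthetic.make_latent_geometry(
        config.n_nodes, config.g_dims, config.network_spread,
        seed=int(master.integers(2**31)),
    )
    ec_effect = _condition_effect(config, geom)
    n_sites = len(config.sites)
    records: list[ScanRecord] = []
    for s_idx, site in enumerate(config.sites):
        for i in range(config.n_subjects):
            subject = f"{site}_sub{i + 1:03d}"
            if config.retest:
                trait = master.normal(0.0, config.retest_between_sd)
                session_dev = master.normal(0.0, config.retest_within_sd, size=2)
            else:
                trait = master.normal(0.0, config.subject_spread_sd)
                session_dev = np.zeros(1)
            for j in range(config.n_sessions):
                scale = float(np.exp(trait + session_dev[j]))
                subject_geom = synthetic.apply_condition_effect(
                    geom,
                    synthetic.ConditionEffect(
                        spread_multipliers={name: scale for name in NETWORKS}
                    ),
                )
                conf_seed = int(master.integers(2**31))
                confs = synthetic.simulate_confounds(
                    design,
                    {"EC": config.fd_mean_ec, "EO": config.fd_mean_eo},
                    seed=conf_seed,
                )
                for condition in design.conditions:
                    cond_geom = (
                        synthetic.apply_condition_effect(subject_geom, ec_effect)
                        if condition == "EC"
                        else subject_geom
                    )
                    scan_seed = int(master.integers(2**31))
                    ts = synthetic.simulate_timeseries(
                        cond_geom, design, config.noise_sd, seed=scan_seed
                    )
                    conf = confs[condition]
                    if config.confound_leak_sd > 0:
                        leak_rng = np.random.default_rng(scan_seed + 1)
                        beta = leak_rng.normal(
                            0.0, config.confound_leak_sd, size=(conf.data.shape[1], ts.n_nodes)
                        )
                        ts = ts.with_data(ts.data + conf.data @ beta)
                    ts = conditioning.regress_confounds(ts, conf)
                    ts = conditioning.bandpass_filter(
                        ts, config.bandpass_low_hz, config.bandpass_high_hz
                    )
                    records.append(
                        ScanRecord(
                            subject=subject,
                            site=site,
                            condition=condition,
                            session=f"ses{j + 1}",
                            matrix=connectome.correlation_matrix(ts),
                            mean_fd=float(conf.fd[1:].mean()),
                        )
                    )
    logger.info(
        "simulated and conditioned %d scans in %.1f s",
        len(records), time.perf_counter() - t0,
    )
    return records, geom


def _embedding_config(config: StudyConfig) -> embedding.EmbeddingConfig:
    return embedding.EmbeddingConfig(
        alpha=config.embedding_alpha,
        diffusion_time=config.diffusion_time,
        n_components=config.n_components,
    )


def _template_from_records(
    config: StudyConfig, records: list[ScanRecord]
) -> embedding.GradientEmbedding:
    template_cm = connectome.group_template_matrix([r.matrix for r in records])
    sparse = connectome.threshold_top_fraction(template_cm, config.threshold_fraction)
    affinity = embedding.cosine_affinity(sparse)
    return embedding.diffusion_embedding(
        affinity, _embedding_config(config), node_ids=template_cm.node_ids
    )


def run_group_template(config: StudyConfig) -> embedding.GradientEmbedding:
    """Build the group gradient template: average all scans' Pearson
    matrices, Fisher z, top-fraction threshold, cosine affinity, diffusion
    embedding."""
    records, _ = _generate_scans(config)
    template = _template_from_records(config, records)
    logger.info(
        "group template: variance explained by first two gradients "
        "%.2f%% and %.2f%%",
        100 * template.variance_ratios[0],
        100 * template.variance_ratios[1],
    )
    return template


def _individual_embedding(
    config: StudyConfig,
    record: ScanRecord,
    template: embedding.GradientEmbedding,
) -> embedding.GradientEmbedding:
    cm = connectome.zscore_matrix(record.matrix)
    sparse = connectome.threshold_top_fraction(cm, config.threshold_fraction)
    affinity = embedding.cosine_affinity(sparse)
    emb = embedding.diffusion_embedding(
        affinity, _embedding_config(config), node_ids=record.matrix.node_ids
    )
    return embedding.procrustes_align(emb, template)


def _paired_frame(table: pd.DataFrame, metric: str, network: str | None = None) -> pd.DataFrame:
    sel = table[(table["metric"] == metric) & (table["session"] == "ses1")]
    if network is not None:
        sel = sel[sel["network"] == network]
    wide = sel.pivot_table(index="subject", columns="condition", values="value")
    return wide


def run_full_study(config: StudyConfig) -> StudyResult:
    """Run the whole pipeline and produce the statistical report.

    The primary family is the 14 condition comparisons (within- and
    between-network dispersion of the seven networks, EC vs EO) with the
    per-subject FD difference as covariate, Bonferroni-corrected at
    ``family_size``; the pairwise centroid-distance follow-up uses its own
    family of 21 network pairs. With ``retest=True``, per-condition ANOVA
    and ReML ICC tables over the two sessions are added.
    """
    records, geom = _generate_scans(config)
    template = _template_from_records(config, records)
    rows = []
    for record in records:
        emb = _individual_embedding(config, record, template)
        rows.append(
            (
                {
                    "subject": record.subject,
                    "site": record.site,
                    "condition": record.condition,
                    "session": record.session,
                },
                emb,
            )
        )
    table = dispersion.dispersion_table(
        rows, geom.labels, dims=config.dims, aggregator=config.aggregator
    )

    # per-subject FD covariate: EC - EO difference at session 1
    fd = pd.DataFrame(
        [
            {"subject": r.subject, "condition": r.condition, "session": r.session, "fd": r.mean_fd}
            for r in records
        ]
    )
    fd1 = fd[fd["session"] == "ses1"].pivot_table(
        index="subject", columns="condition", values="fd"
    )
    fd_test = reliability.rm_anova_two_condition(fd1["EC"].to_numpy(), fd1["EO"].to_numpy())
    delta_fd = fd1["EC"] - fd1["EO"]

    threshold = reliability.bonferroni_threshold(config.alpha_level, config.family_size)
    comp_rows = []
    for metric in ("within", "between"):
        for name in NETWORKS:
            wide = _paired_frame(table, metric, name)
            res = reliability.rm_anova_two_condition(
                wide["EC"].to_numpy(),
                wide["EO"].to_numpy(),
                covariate=delta_fd.loc[wide.index].to_numpy(),
            )
            comp_rows.append(
                {
                    "family": "primary",
                    "metric": metric,
                    "network": name,
                    "other": None,
                    "f": res.f,
                    "df1": res.df1,
                    "df2": res.df2,
                    "p": res.p,
                    "mean_ec": res.mean_a,
                    "mean_eo": res.mean_b,
                    "p_threshold": threshold,
                    "significant": res.p < threshold,
                }
            )
    pair_threshold = reliability.bonferroni_threshold(
        config.alpha_level, len(list(combinations(NETWORKS, 2)))
    )
    for a, b in combinations(NETWORKS, 2):
        wide = _paired_frame(table, f"dist:{b}", a)
        res = reliability.rm_anova_two_condition(
            wide["EC"].to_numpy(),
            wide["EO"].to_numpy(),
            covariate=delta_fd.loc[wide.index].to_numpy(),
        )
        comp_rows.append(
            {
                "family": "pairwise",
                "metric": "centroid_distance",
                "network": a,
                "other": b,
                "f": res.f,
                "df1": res.df1,
                "df2": res.df2,
                "p": res.p,
                "mean_ec": res.mean_a,
                "mean_eo": res.mean_b,
                "p_threshold": pair_threshold,
                "significant": res.p < pair_threshold,
            }
        )
    comparisons = pd.DataFrame(comp_rows)

    icc_frame = None
    icc_comparisons = None
    if config.retest:
        icc_rows = []
        for condition in ("EC", "EO"):
            for metric in ("within", "between"):
                for name in NETWORKS:
                    sel = table[
                        (table["metric"] == metric)
                        & (table["network"] == name)
                        & (table["condition"] == condition)
                    ]
                    wide = sel.pivot_table(
                        index="subject", columns="session", values="value"
                    )
                    y = wide.to_numpy()
                    for method, fn in (
                        ("anova", reliability.anova_icc),
                        ("reml", reliability.reml_icc),
                    ):
                        res = fn(y)
                        icc_rows.append(
                            {
                                "method": method,
                                "condition": condition,
                                "metric": metric,
                                "network": name,
                                "icc": res.icc,
                                "bms": res.bms,
                                "ems": res.ems,
                                "k": res.k,
                            }
                        )
        icc_frame = pd.DataFrame(icc_rows)
        cmp_rows = []
        for metric in ("within", "between"):
            sub = icc_frame[(icc_frame["method"] == "anova") & (icc_frame["metric"] == metric)]
            eo = sub[sub["condition"] == "EO"].set_index("network")["icc"]
            ec = sub[sub["condition"] == "EC"].set_index("network")["icc"]
            res = reliability.compare_icc_sets(
                ec.loc[list(NETWORKS)].to_numpy(), eo.loc[list(NETWORKS)].to_numpy()
            )
            cmp_rows.append(
                {"metric": metric, "f": res.f, "df1": res.df1, "df2": res.df2, "p": res.p}
            )
        icc_comparisons = pd.DataFrame(cmp_rows)

    return StudyResult(
        config=config,
        template=template,
        dispersion=table,
        comparisons=comparisons,
        fd_test=fd_test,
        icc=icc_frame,
        icc_comparisons=icc_comparisons,
        labels=geom.labels,
    )
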