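"""Cohort-level fragmentation analysis as a model/results pair.

``FragmentationModel`` is built from a :class:`~connfrag.io.CohortData`
(real-format or synthetic) plus an :class:`AnalysisConfig`; ``fit()`` runs
the full per-subject and cohort pipeline and returns a
``FragmentationResults`` carrying five tidy tables:

* ``subject_table`` — per subject: left/right/whole modularity (best, mean,
  sd over the consensus runs), community affiliation indices C_L/C_R, the
  fragmentation index FI, module counts, mean left node strength, number of
  left-hemisphere rich-club hubs, and per-ROI metrics (participation,
  intra-modular degree, module size, co-membership) for the configured
  language ROIs.
* ``correlation_table`` — directional (one-tailed) Pearson and partial
  correlations of every network metric against WAB-AQ and its subscores,
  with damage covariate sets.
* ``regression_table`` — the three nested severity models
  (damage; damage + hubs; damage + modularity) with adjusted R².
* ``pairwise_table`` — gated, Bonferroni-corrected pairwise co-membership
  t-tests over left-hemisphere region pairs.
* ``network_table`` — per-region co-membership-frequency and module-size
  correlations for the language-specific and domain-general subnetworks
  (uncorrected, flagged as such in the log).

Determinism: per-subject random substreams are derived from the config
seed and a stable hash of the subject id, so results are bit-identical
across runs and invariant to subject ordering.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .community import (
    AffiliationResult,
    affiliation_index,
    consensus_affiliation,
    fragmentation_index,
    module_count,
)
from .io import CohortData, Connectome, Parcellation, hemisphere_submatrix, load_cohort
from .metrics import (
    co_membership_frequency,
    identify_hubs,
    intra_modular_degree,
    module_size,
    node_strength,
    participation_coefficient,
)
from .stats import (
    fit_ols,
    pairwise_module_ttests,
    partial_correlation_one_tailed,
    pearson_one_tailed,
    ttest_unpaired,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "ResultBundle",
    "FragmentationModel",
    "FragmentationResults",
    "analyze_subject",
    "run_analysis",
    "run_group_comparison",
    "fit_severity_models",
]

_FLOAT_FMT = "%.17g"

#: a-priori association direction of each network metric with behavior
#: (higher modularity / fragmentation with worse scores; higher affiliation
#: stability / strength with better scores)
_DEFAULT_DIRECTIONS = {
    "Q_L": "negative",
    "Q_R": "negative",
    "Q_whole": "negative",
    "C_L": "positive",
    "C_R": "positive",
    "FI": "negative",
    "mean_strength_L": "positive",
}

_SCORES = ("wab_aq", "comprehension", "fluency", "naming", "repetition")


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable pipeline parameters (defaults follow the study protocol:
    100 consensus optimizations at resolution gamma = 1, minimum group of
    5 for pairwise tests, 50% preservation gate, alpha = 0.05)."""

    n_runs: int = 100
    gamma: float = 1.0
    min_group: int = 5
    preservation_threshold: float = 0.5
    alpha: float = 0.05
    n_null_rewirings: int = 100
    seed: int = 0
    roi_targets: tuple[str, ...] = ("pars_triangularis", "pars_opercularis", "STG")
    directions: dict = field(default_factory=lambda: dict(_DEFAULT_DIRECTIONS))
    equal_var: bool = True
    preservation_scope: str = "subject"
    compute_whole: bool = True
    compute_hubs: bool = True
    compute_pairwise: bool = True
    min_subjects_for_correlations: int = 10

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")

    def replace(self, **kwargs) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["roi_targets"] = list(self.roi_targets)
        return d


def _subject_rng(cfg: AnalysisConfig, subject_id: str, purpose: int) -> np.random.Generator:
    """Substream keyed by (seed, stable hash of subject id, purpose), so
    per-subject results do not depend on cohort ordering."""
    sid_hash = zlib.crc32(subject_id.encode())
    return np.random.default_rng(
        np.random.SeedSequence(entropy=[cfg.seed, sid_hash, purpose])
    )


def analyze_subject(
    subject, parc: Parcellation, cfg: AnalysisConfig
) -> tuple[dict, dict | None]:
    """Per-subject network metrics.

    Returns ``(row, artifacts)`` where ``artifacts`` holds the left/right
    affiliation results for downstream pairwise and network tables.  A
    degenerate hemisphere (zero total weight) yields a flagged row and
    ``None`` artifacts.
    """
    sid = subject.subject_id
    left = hemisphere_submatrix(subject.connectome, parc, "L")
    right = hemisphere_submatrix(subject.connectome, parc, "R")
    row: dict = {"subject_id": sid, "flagged": ""}
    if left.total_weight <= 0 or right.total_weight <= 0:
        side = "left" if left.total_weight <= 0 else "right"
        row["flagged"] = f"degenerate_{side}_hemisphere"
        logger.warning("subject %s: %s; excluded from cohort statistics", sid, row["flagged"])
        return row, None

    aff_l = consensus_affiliation(
        left, n_runs=cfg.n_runs, gamma=cfg.gamma, rng=_subject_rng(cfg, sid, 0)
    )
    aff_r = consensus_affiliation(
        right, n_runs=cfg.n_runs, gamma=cfg.gamma, rng=_subject_rng(cfg, sid, 1)
    )
    c_l = affiliation_index(aff_l)
    c_r = affiliation_index(aff_r)
    frag = fragmentation_index(c_r, c_l)
    row.update(
        {
            "Q_L": aff_l.Q_best,
            "Q_L_mean": aff_l.Q_mean,
            "Q_L_sd": aff_l.Q_sd,
            "Q_R": aff_r.Q_best,
            "Q_R_mean": aff_r.Q_mean,
            "Q_R_sd": aff_r.Q_sd,
            "C_L": c_l,
            "C_R": c_r,
            "FI": frag.fi,
            "module_count_L": module_count(aff_l.best_partition),
            "module_count_R": module_count(aff_r.best_partition),
            "mean_strength_L": float(node_strength(left).mean()),
        }
    )
    if cfg.compute_whole:
        aff_w = consensus_affiliation(
            subject.connectome,
            n_runs=cfg.n_runs,
            gamma=cfg.gamma,
            rng=_subject_rng(cfg, sid, 2),
        )
        row["Q_whole"] = aff_w.Q_best
    if cfg.compute_hubs:
        try:
            hubs = identify_hubs(
                left,
                n_null=cfg.n_null_rewirings,
                rng=_subject_rng(cfg, sid, 3),
                alpha=cfg.alpha,
            )
        except ValueError as exc:
            logger.warning("subject %s: hub detection degenerate (%s); 0 hubs", sid, exc)
            hubs = set()
        row["n_hubs_L"] = len(hubs)

    # ROI-level metrics on the best left partition
    part = aff_l.best_partition
    for tag in cfg.roi_targets:
        rid = parc.find_roi(tag, "L")
        if rid is None:
            continue
        idx = left.index(rid)
        label = int(part.labels[idx])
        mm = intra_modular_degree(left, part, label, damage=subject.damage)
        row[f"participation_{tag}"] = participation_coefficient(left, part, idx)
        row[f"intra_modular_degree_{tag}"] = mm.intra_modular_degree_mean
        row[f"module_size_{tag}"] = module_size(part, idx)
        row[f"co_membership_{tag}"] = co_membership_frequency(aff_l, idx)
        row[f"module_damage_{tag}"] = mm.module_damage
    return row, {"affiliation_L": aff_l, "affiliation_R": aff_r}


def _corr_row(metric, score, direction, covariates, x, y, Z, cov_names):
    try:
        if Z is None:
            res = pearson_one_tailed(x, y, direction)
        else:
            res = partial_correlation_one_tailed(
                x, y, Z, direction, covariate_names=cov_names
            )
    except ValueError as exc:
        logger.warning("correlation %s vs %s (%s) skipped: %s", metric, score, covariates, exc)
        return None
    return {
        "metric": metric,
        "score": score,
        "covariates": covariates,
        "direction": direction,
        "r": res.r,
        "p": res.p,
        "n": res.n,
    }


def fit_severity_models(df: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """The three nested severity regressions on a subject table.

    Model 1: wab_aq ~ damage; model 2: + number of left hubs;
    model 3: damage + left modularity.  Tidy output, one row per term.
    """
    specs = [
        ("damage", ["grey_damage_total"]),
        ("damage+hubs", ["grey_damage_total", "n_hubs_L"]),
        ("damage+modularity", ["grey_damage_total", "Q_L"]),
    ]
    rows = []
    for name, predictors in specs:
        missing = [p for p in predictors if p not in df.columns]
        if missing:
            logger.warning("model %s skipped: missing predictors %s", name, missing)
            continue
        try:
            summ = fit_ols(
                df["wab_aq"].to_numpy(), df[predictors], response="wab_aq"
            )
        except ValueError as exc:
            logger.warning("model %s skipped: %s", name, exc)
            continue
        for term in predictors:
            est, p = summ.coefficients[term]
            rows.append(
                {
                    "model": name,
                    "term": term,
                    "estimate": est,
                    "p_value": p,
                    "F": summ.F,
                    "p_model": summ.p_model,
                    "R2": summ.R2,
                    "adjusted_R2": summ.adjusted_R2,
                    "n": summ.n,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "model", "term", "estimate", "p_value", "F", "p_model",
            "R2", "adjusted_R2", "n",
        ],
    )


def run_analysis(
    cohort: CohortData, cfg: AnalysisConfig | None = None
) -> tuple["ResultBundle", dict]:
    """Full cohort analysis; returns (bundle, per-subject artifacts)."""
    cfg = cfg or AnalysisConfig()
    parc = cohort.parcellation
    order = sorted(cohort.subject_ids)
    rows = []
    artifacts: dict[str, dict] = {}
    for sid in order:
        row, art = analyze_subject(cohort.subject(sid), parc, cfg)
        rows.append(row)
        if art is not None:
            artifacts[sid] = art
    subject_table = pd.DataFrame(rows)
    # behavior + damage covariates joined per subject
    for col in _SCORES:
        subject_table[col] = [
            cohort.score_series(col).get(sid, np.nan) for sid in subject_table["subject_id"]
        ]
    lang_ids = parc.language_specific_ids
    extras = {"grey_damage_total": [], "white_damage_total": [], "language_damage": [],
              "lesion_volume_cm3": []}
    for sid in subject_table["subject_id"]:
        s = cohort.subject(sid)
        extras["grey_damage_total"].append(s.grey_damage_total)
        extras["white_damage_total"].append(s.white_damage_total)
        extras["lesion_volume_cm3"].append(s.lesion_volume_cm3)
        extras["language_damage"].append(
            float(np.mean([s.damage.get(r, 0.0) for r in lang_ids])) if lang_ids else 0.0
        )
    for k, v in extras.items():
        subject_table[k] = v

    ok = subject_table["flagged"] == ""
    valid = subject_table[ok].reset_index(drop=True)
    n_valid = len(valid)

    # (a) directional correlations, plain and partial
    corr_rows = []
    if n_valid >= cfg.min_subjects_for_correlations:
        cov_sets = [
            ("none", []),
            ("grey_damage_total", ["grey_damage_total"]),
            ("white_damage_total", ["white_damage_total"]),
            ("language_damage", ["language_damage"]),
        ]
        for metric, direction in cfg.directions.items():
            if metric not in valid.columns or valid[metric].isna().all():
                continue
            x = valid[metric].to_numpy(dtype=float)
            for score in _SCORES:
                y = valid[score].to_numpy(dtype=float)
                for cov_label, cov_cols in cov_sets:
                    Z = valid[cov_cols].to_numpy(dtype=float) if cov_cols else None
                    r = _corr_row(
                        metric, score, direction, cov_label, x, y, Z, tuple(cov_cols)
                    )
                    if r is not None:
                        corr_rows.append(r)
        # ROI-level correlations vs overall severity, optionally controlling
        # for damage to the ROI's own module
        for tag in cfg.roi_targets:
            for metric_stub in ("participation", "intra_modular_degree", "module_size"):
                col = f"{metric_stub}_{tag}"
                if col not in valid.columns:
                    continue
                x = valid[col].to_numpy(dtype=float)
                y = valid["wab_aq"].to_numpy(dtype=float)
                r = _corr_row(col, "wab_aq", "positive", "none", x, y, None, ())
                if r is not None:
                    corr_rows.append(r)
                dmg_col = f"module_damage_{tag}"
                if dmg_col in valid.columns:
                    Z = valid[[dmg_col]].to_numpy(dtype=float)
                    r = _corr_row(
                        col, "wab_aq", "positive", "module_damage", x, y, Z, (dmg_col,)
                    )
                    if r is not None:
                        corr_rows.append(r)
    else:
        logger.warning(
            "only %d valid subjects (< %d): correlation outputs suppressed",
            n_valid, cfg.min_subjects_for_correlations,
        )
    correlation_table = pd.DataFrame(
        corr_rows, columns=["metric", "score", "covariates", "direction", "r", "p", "n"]
    )

    # (b) nested severity regressions
    regression_table = (
        fit_severity_models(valid, alpha=cfg.alpha)
        if n_valid >= cfg.min_subjects_for_correlations
        else pd.DataFrame()
    )

    # (c) pairwise co-membership tests (left hemisphere)
    if cfg.compute_pairwise and artifacts:
        pairwise_table = pairwise_module_ttests(
            cohort,
            {sid: art["affiliation_L"] for sid, art in artifacts.items()},
            score_name="wab_aq",
            min_group=cfg.min_group,
            preservation_threshold=cfg.preservation_threshold,
            alpha=cfg.alpha,
            preservation_scope=cfg.preservation_scope,
            equal_var=cfg.equal_var,
        )
    else:
        pairwise_table = pd.DataFrame()

    # (d) language-specific / domain-general per-region correlations
    net_rows = []
    if n_valid >= cfg.min_subjects_for_correlations and artifacts:
        logger.warning(
            "network_table correlations are not corrected for multiple comparisons"
        )
        y = valid["wab_aq"].to_numpy(dtype=float)
        networks = [("language_specific", lang_ids), ("domain_general", parc.domain_general_ids)]
        for net_name, rids in networks:
            for rid in rids:
                cm, ms = [], []
                for sid in valid["subject_id"]:
                    aff = artifacts[sid]["affiliation_L"]
                    idx = aff.index(rid)
                    cm.append(co_membership_frequency(aff, idx))
                    ms.append(module_size(aff.best_partition, idx))
                for metric_name, vals in (
                    ("co_membership_freq", cm),
                    ("module_size", ms),
                ):
                    r = _corr_row(
                        metric_name, "wab_aq", "positive", "none",
                        np.asarray(vals, dtype=float), y, None, (),
                    )
                    if r is not None:
                        r["region_id"] = rid
                        r["network"] = net_name
                        net_rows.append(r)
    network_table = pd.DataFrame(
        net_rows,
        columns=["region_id", "network", "metric", "score", "covariates",
                 "direction", "r", "p", "n"],
    )

    bundle = ResultBundle(
        subject_table=subject_table,
        correlation_table=correlation_table,
        regression_table=regression_table,
        pairwise_table=pairwise_table,
        network_table=network_table,
        config=cfg,
    )
    return bundle, artifacts


def run_group_comparison(
    subject_table: pd.DataFrame, groups: dict[str, str], metric: str
) -> dict:
    """Two-tailed unpaired t-test of a metric between two subject groups
    (e.g. the acquisition-sequence check run before pooling a cohort)."""
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    df = subject_table[subject_table["flagged"] == ""]
    vals = {
        lab: df[df["subject_id"].map(groups) == lab][metric].to_numpy(dtype=float)
        for lab in labels
    }
    if any(v.size == 0 for v in vals.values()):
        raise ValueError("a group has no subjects with valid metrics")
    t, p = ttest_unpaired(vals[labels[0]], vals[labels[1]], tails=2)
    return {
        "metric": metric,
        "group_a": labels[0],
        "group_b": labels[1],
        "n_a": int(vals[labels[0]].size),
        "n_b": int(vals[labels[1]].size),
        "t": t,
        "p": p,
    }


@dataclass
class ResultBundle:
    """The five tidy output tables plus the configuration that made them."""

    subject_table: pd.DataFrame
    correlation_table: pd.DataFrame
    regression_table: pd.DataFrame
    pairwise_table: pd.DataFrame
    network_table: pd.DataFrame
    config: AnalysisConfig

    _TABLES = (
        ("subject_table", "subject_metrics.csv"),
        ("correlation_table", "correlations.csv"),
        ("regression_table", "regressions.csv"),
        ("pairwise_table", "pairwise_tests.csv"),
        ("network_table", "network_regions.csv"),
    )

    def save(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for attr, fname in self._TABLES:
            getattr(self, attr).to_csv(
                out_dir / fname, index=False, float_format=_FLOAT_FMT
            )
        cfg_dict = self.config.to_dict()
        cfg_json = json.dumps(cfg_dict, sort_keys=True)
        meta = {
            "package_version": __version__,
            "seed": self.config.seed,
            "config": cfg_dict,
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        }
        with open(out_dir / "run_metadata.json", "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)
        return out_dir


class FragmentationModel:
    """Lesioned-connectome fragmentation analysis over a cohort.

    Parameters
    ----------
    cohort : CohortData
        Parcellation-aligned subjects with behavior, damage and connectomes.
    config : AnalysisConfig, optional
        Pipeline parameters; defaults follow the study protocol.

    Examples
    --------
    >>> from connfrag import FragmentationModel, AnalysisConfig
    >>> from connfrag.simulate import SyntheticConfig, generate_cohort
    >>> cohort = generate_cohort(SyntheticConfig(n_subjects=20, seed=7))
    >>> res = FragmentationModel(cohort, AnalysisConfig(n_runs=25)).fit()
    >>> res.correlation("FI", "wab_aq")["r"] < 0
    True
    """

    def __init__(self, cohort: CohortData, config: AnalysisConfig | None = None):
        self.cohort = cohort
        self.config = config or AnalysisConfig()

    @classmethod
    def from_directory(
        cls, path: str | Path, config: AnalysisConfig | None = None
    ) -> "FragmentationModel":
        return cls(load_cohort(path), config)

    def fit(self) -> "FragmentationResults":
        bundle, artifacts = run_analysis(self.cohort, self.config)
        return FragmentationResults(self, bundle, artifacts)


class FragmentationResults:
    """Fitted cohort results; see the module docstring for table layouts."""

    def __init__(self, model: FragmentationModel, bundle: ResultBundle, artifacts: dict):
        self.model = model
        self.bundle = bundle
        self._artifacts = artifacts

    # -- table access ------------------------------------------------------

    @property
    def subject_table(self) -> pd.DataFrame:
        return self.bundle.subject_table

    @property
    def correlation_table(self) -> pd.DataFrame:
        return self.bundle.correlation_table

    @property
    def regression_table(self) -> pd.DataFrame:
        return self.bundle.regression_table

    @property
    def pairwise_table(self) -> pd.DataFrame:
        return self.bundle.pairwise_table

    @property
    def network_table(self) -> pd.DataFrame:
        return self.bundle.network_table

    def affiliation(self, subject_id: str, hemisphere: str = "L") -> AffiliationResult:
        key = f"affiliation_{hemisphere}"
        return self._artifacts[subject_id][key]

    def correlation(
        self, metric: str, score: str = "wab_aq", covariates: str = "none"
    ) -> dict:
        df = self.correlation_table
        hit = df[
            (df["metric"] == metric)
            & (df["score"] == score)
            & (df["covariates"] == covariates)
        ]
        if hit.empty:
            raise KeyError(f"no correlation row for ({metric}, {score}, {covariates})")
        return hit.iloc[0].to_dict()

    def group_comparison(self, groups: dict[str, str], metric: str = "Q_L") -> dict:
        return run_group_comparison(self.subject_table, groups, metric)

    def save(self, out_dir: str | Path) -> Path:
        return self.bundle.save(out_dir)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        st = self.subject_table
        ok = st[st["flagged"] == ""]
        lines = [
            "Connectome fragmentation analysis",
            "=" * 70,
            f"subjects: {len(st)} ({len(st) - len(ok)} flagged/excluded)   "
            f"consensus runs: {self.model.config.n_runs}   "
            f"gamma: {self.model.config.gamma:g}",
            "",
            "Per-subject metrics (mean over cohort):",
        ]
        for col, label in [
            ("Q_L", "left-hemisphere modularity Q"),
            ("Q_R", "right-hemisphere modularity Q"),
            ("C_L", "left community affiliation index C"),
            ("C_R", "right community affiliation index C"),
            ("FI", "fragmentation index FI"),
            ("wab_aq", "WAB-AQ"),
        ]:
            if col in ok.columns:
                lines.append(f"  {label:38s} {ok[col].mean():8.4f} (sd {ok[col].std():.4f})")
        ct = self.correlation_table
        if not ct.empty:
            lines += ["", "Key brain-behavior correlations vs WAB-AQ (one-tailed):"]
            for metric in ("Q_L", "C_L", "FI", "mean_strength_L"):
                sel = ct[
                    (ct["metric"] == metric)
                    & (ct["score"] == "wab_aq")
                    & (ct["covariates"] == "none")
                ]
                if not sel.empty:
                    row = sel.iloc[0]
                    lines.append(
                        f"  {metric:16s} r = {row['r']:+.4f}   p = {row['p']:.4g}   "
                        f"(expected {row['direction']})"
                    )
        rt = self.regression_table
        if not rt.empty:
            lines += ["", "Severity regressions (WAB-AQ response):"]
            for name, sub in rt.groupby("model", sort=False):
                r = sub.iloc[0]
                terms = ", ".join(
                    f"{t['term']} (p={t['p_value']:.3g})" for _, t in sub.iterrows()
                )
                lines.append(
                    f"  {name:20s} adj R2 = {r['adjusted_R2']:.3f}   "
                    f"F = {r['F']:.1f}   terms: {terms}"
                )
        pt = self.pairwise_table
        if not pt.empty:
            n_run = int((pt["skipped_reason"] == "").sum())
            n_sig = int(pt["significant"].sum())
            lines += [
                "",
                f"Pairwise co-membership tests: {len(pt)} pairs, {n_run} executed, "
                f"{n_sig} significant after Bonferroni",
            ]
        return "\n".join(lines)

    # -- plotting ----------------------------------------------------------

    def plot_fragmentation(self, score: str = "wab_aq", ax=None):
        """Scatter of fragmentation index vs a behavior score with OLS line."""
        import matplotlib.pyplot as plt

        st = self.subject_table
        ok = st[st["flagged"] == ""]
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        x = ok["FI"].to_numpy(dtype=float)
        y = ok[score].to_numpy(dtype=float)
        ax.scatter(x, y, s=18, alpha=0.7)
        if x.std() > 0:
            b, a = np.polyfit(x, y, 1)
            xs = np.linspace(x.min(), x.max(), 50)
            ax.plot(xs, a + b * xs, color="crimson")
        ax.set_xlabel("fragmentation index FI")
        ax.set_ylabel(score)
        return ax

    def plot_affiliation(self, subject_id: str, hemisphere: str = "L", ax=None):
        """Heatmap of a subject's consensus community affiliation matrix."""
        import matplotlib.pyplot as plt

        aff = self.affiliation(subject_id, hemisphere)
        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4))
        im = ax.imshow(aff.A, vmin=0, vmax=1, cmap="viridis")
        ax.set_title(f"{subject_id} {hemisphere} affiliation (n_runs={aff.n_runs})")
        ax.figure.colorbar(im, ax=ax, label="co-assignment probability")
        return ax
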