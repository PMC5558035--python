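"""Synthetic lesioned-cohort generator with full ground truth.

Emulates the statistical structure the fragmentation analysis assumes,
without any imaging: each subject gets paired left/right hemispheric
connectomes drawn from one planted-partition (stochastic block) model, a
spatially contiguous lesion applied to the left hemisphere only, per-region
damage fractions, and behavior scores (WAB-AQ plus four subscores on
0-100) generated as a noisy decreasing function of the subject's internal
left-hemisphere fragmentation.  Ground truth (injected lesion extent,
internal fragmentation/modularity, behavior coefficients, seed) rides along
in ``CohortData.ground_truth`` for parameter-recovery tests.

The lesion acts multiplicatively on edge weights through node damage
(``w'_ij = w_ij * (1 - d_i) * (1 - d_j)``), reproducing the fragmentation
phenomenology of tractography restricted to surviving tissue — attenuated
modules, unstable consensus clustering, isolated nodes at full damage —
without modeling tracts.  Spatial contiguity of damage is defined on region
index order, a 1-D proxy for anatomical adjacency (no atlas geometry is
shipped).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import affiliation_index, consensus_affiliation, fragmentation_index, Partition
from .io import (
    CohortData,
    Connectome,
    Parcellation,
    Region,
    SubjectRecord,
    SUBSCORE_NAMES,
    default_parcellation,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticConfig",
    "make_parcellation",
    "generate_hemisphere",
    "generate_damage_profile",
    "apply_lesion",
    "generate_behavior",
    "generate_cohort",
    "generate_planted_pair_cohort",
]


# Left-hemisphere index slots for the tagged ROIs when synthesizing a
# parcellation (language-specific first 9, domain-general last 8).
_LANGUAGE_TAGS = (
    ("MFG_post", "posterior middle frontal gyrus"),
    ("pars_opercularis", "inferior frontal gyrus pars opercularis"),
    ("pars_triangularis", "inferior frontal gyrus pars triangularis"),
    ("STG", "superior temporal gyrus"),
    ("STG_pole", "superior temporal gyrus pole"),
    ("MTG", "middle temporal gyrus"),
    ("PMTG", "posterior middle temporal gyrus"),
    ("PITG", "posterior inferior temporal gyrus"),
    ("AG", "angular gyrus"),
)
_DOMAIN_TAGS = (
    ("SFG_post", "posterior superior frontal gyrus"),
    ("MFG_DPFC", "middle frontal gyrus dorsal prefrontal cortex"),
    ("IFG_orbitalis", "inferior frontal gyrus pars orbitalis"),
    ("PrCG", "precentral gyrus"),
    ("SPG", "superior parietal gyrus"),
    ("SMG", "supramarginal gyrus"),
    ("PCC", "posterior cingulate cortex"),
    ("insula", "insula"),
)
_TAG_SLOTS = (10, 11, 12, 20, 21, 22, 23, 24, 30, 5, 6, 13, 15, 31, 32, 40, 45)


def make_parcellation(n_per_hemisphere: int) -> Parcellation:
    """Synthesize a two-hemisphere parcellation of the requested size.

    At 57 regions per hemisphere this reproduces the bundled default:
    left-hemisphere slots carry the 9 language-specific and 8 domain-general
    ROI tags; right-hemisphere regions are untagged.
    """
    if n_per_hemisphere < 2:
        raise ValueError("need at least 2 regions per hemisphere")
    tags = list(_LANGUAGE_TAGS) + list(_DOMAIN_TAGS)
    slot_of: dict[int, tuple[str, str, bool]] = {}
    for (tag, name), slot in zip(tags, _TAG_SLOTS):
        if slot < n_per_hemisphere:
            is_lang = any(tag == t for t, _ in _LANGUAGE_TAGS)
            slot_of[slot] = (tag, name, is_lang)
    regions = []
    for hemi in ("L", "R"):
        for i in range(n_per_hemisphere):
            rid = f"{hemi}{i + 1:03d}"
            if hemi == "L" and i in slot_of:
                tag, name, is_lang = slot_of[i]
                regions.append(
                    Region(
                        region_id=rid,
                        name=name,
                        hemisphere=hemi,
                        language_specific=is_lang,
                        domain_general=not is_lang,
                        roi_tag=tag,
                    )
                )
            else:
                regions.append(
                    Region(
                        region_id=rid,
                        name=f"{'left' if hemi == 'L' else 'right'} region {i + 1}",
                        hemisphere=hemi,
                    )
                )
    return Parcellation(tuple(regions))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a synthetic lesioned cohort.

    Weight units are arbitrary; what matters is the within/between-module
    contrast (``w_in`` vs ``w_out``) and the edge densities.  The defaults
    give sparse hemispheric networks with a planted 4-module structure of
    *moderate* salience — intact-hemisphere modularity around 0.34, as
    observed in real adult structural connectomes — so that a destructive
    lesion fragments the surviving left-hemisphere network into many small
    modules and isolated nodes (raising Q, lowering C) instead of merely
    attenuating a cartoonishly crisp block pattern.  Lesions combine a
    necrotic core (complete destruction with probability
    ``complete_destruction_prob``) with a partially damaged penumbra.
    Behavior is scored like the WAB-AQ: a 0-100 scale with a ceiling,
    lower meaning worse aphasia.  ``behavior_beta_fi`` is the score drop
    per standard deviation of internal fragmentation; optional damage and
    modularity coefficients support regression-style generative models and
    default to zero.
    """

    n_subjects: int = 90
    n_regions_per_hemisphere: int = 57
    n_modules_healthy: int = 4
    w_in: float = 1.0
    w_out: float = 0.8
    weight_noise_cv: float = 0.4
    density_within: float = 0.30
    density_between: float = 0.10
    w_inter: float = 0.05
    lesion_extent_range: tuple[float, float] = (0.05, 0.8)
    damage_severity_range: tuple[float, float] = (0.8, 1.0)
    complete_destruction_prob: float = 0.9
    rich_club_size: int = 8
    rich_club_degree_factor: float = 2.0
    rich_club_density: float = 1.0
    rich_club_weight_factor: float = 0.25
    behavior_beta0: float = 100.0
    behavior_beta_fi: float = -15.0
    behavior_beta_damage: float = 0.0
    behavior_beta_q: float = 0.0
    behavior_noise_sd: float = 20.0
    subscore_latent_loading: float = 0.9
    region_volume_cm3: float = 7.0
    fi_n_runs: int = 25
    gamma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_regions_per_hemisphere < 2 * self.n_modules_healthy:
            raise ValueError(
                "need at least 2 regions per planted module per hemisphere"
            )
        if not self.w_in > self.w_out >= 0:
            raise ValueError("require w_in > w_out >= 0")
        if self.weight_noise_cv < 0 or self.behavior_noise_sd < 0:
            raise ValueError("noise parameters must be nonnegative")
        for name in ("lesion_extent_range", "damage_severity_range"):
            lo, hi = getattr(self, name)
            if not 0.0 <= lo <= hi <= 1.0:
                raise ValueError(f"{name} must be an interval within [0, 1]")
        for name in ("density_within", "density_between"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        if not 0.0 <= self.complete_destruction_prob <= 1.0:
            raise ValueError("complete_destruction_prob must lie in [0, 1]")
        if self.fi_n_runs < 1:
            raise ValueError("fi_n_runs must be >= 1")
        if not 0.0 <= self.subscore_latent_loading <= 1.0:
            raise ValueError("subscore_latent_loading must lie in [0, 1]")

    def replace(self, **kwargs) -> "SyntheticConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _planted_block_labels(n: int, m: int) -> np.ndarray:
    # interleaved in index order: spatial position (index) and functional
    # module membership are deliberately orthogonal, so a spatially
    # contiguous lesion cuts across every module — as real strokes cut
    # across functional systems — rather than deleting modules wholesale
    return np.arange(n) % m


def _hub_indices(n: int, size: int) -> np.ndarray:
    if size < 2:
        return np.array([], dtype=int)
    return np.unique(np.round(np.linspace(0, n - 1, size)).astype(int))


def _block_matrix(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    n = cfg.n_regions_per_hemisphere
    labels = _planted_block_labels(n, cfg.n_modules_healthy)
    same = labels[:, None] == labels[None, :]
    mean = np.where(same, cfg.w_in, cfg.w_out).astype(float)
    density = np.where(same, cfg.density_within, cfg.density_between).astype(float)
    hubs = _hub_indices(n, cfg.rich_club_size)
    if hubs.size:
        # planted rich club: hubs gain many *light* spokes (binary degree is
        # what hub detection sees) and a densely interconnected core, while
        # edge weights stay tied to the underlying block means so the
        # modular weight structure is not washed out
        is_hub = np.zeros(n, dtype=bool)
        is_hub[hubs] = True
        spoke = is_hub[:, None] ^ is_hub[None, :]
        density[spoke] = np.minimum(
            density[spoke] * cfg.rich_club_degree_factor, 1.0
        )
        core = np.ix_(hubs, hubs)
        density[core] = cfg.rich_club_density
        mean[spoke] *= cfg.rich_club_weight_factor
        mean[core] = mean[core] * cfg.rich_club_weight_factor
    iu = np.triu_indices(n, k=1)
    w = np.zeros((n, n))
    draws = rng.normal(mean[iu], cfg.weight_noise_cv * mean[iu])
    present = rng.random(iu[0].shape) < density[iu]
    vals = np.clip(draws, 0.0, None) * present
    w[iu] = vals
    w += w.T
    return w


def generate_hemisphere(
    cfg: SyntheticConfig, rng=None, hemisphere: str = "L"
) -> tuple[Connectome, Partition]:
    """One healthy hemispheric connectome plus its planted partition.

    Regions split evenly into ``n_modules_healthy`` contiguous blocks;
    weights are drawn around ``w_in`` within blocks and ``w_out`` between,
    truncated at zero, with edges thinned to the configured densities.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n = cfg.n_regions_per_hemisphere
    w = _block_matrix(cfg, rng)
    ids = tuple(f"{hemisphere}{i + 1:03d}" for i in range(n))
    truth = Partition(_planted_block_labels(n, cfg.n_modules_healthy))
    return Connectome(ids, w), truth


def generate_damage_profile(
    cfg: SyntheticConfig, rng=None, region_ids: tuple[str, ...] | None = None
) -> dict[str, float]:
    """Spatially contiguous left-hemisphere damage fractions.

    A lesion extent (fraction of left regions) is drawn from
    ``lesion_extent_range``; a contiguous index window of that size is
    placed uniformly at random.  Each damaged region is completely
    destroyed (severity exactly 1, the necrotic lesion core) with
    probability ``complete_destruction_prob``, otherwise partially damaged
    with a severity drawn from ``damage_severity_range`` (the penumbra).
    Returns only nonzero entries; absent regions (including the whole right
    hemisphere) are undamaged.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n = cfg.n_regions_per_hemisphere
    if region_ids is None:
        region_ids = tuple(f"L{i + 1:03d}" for i in range(n))
    extent = rng.uniform(*cfg.lesion_extent_range)
    size = int(round(extent * n))
    if size == 0:
        return {}
    start = int(rng.integers(0, n - size + 1))
    severities = rng.uniform(*cfg.damage_severity_range, size=size)
    severities[rng.random(size) < cfg.complete_destruction_prob] = 1.0
    return {
        region_ids[start + k]: float(severities[k]) for k in range(size)
    }


def apply_lesion(c: Connectome, damage: dict[str, float]) -> Connectome:
    """Attenuate edges by node damage: w'_ij = w_ij (1 - d_i)(1 - d_j)."""
    d = np.zeros(len(c))
    for rid, frac in damage.items():
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"damage[{rid}] = {frac} outside [0, 1]")
        try:
            d[c.index(rid)] = frac
        except KeyError:
            continue  # damage to regions outside this (sub)network
    survive = 1.0 - d
    return Connectome(c.region_ids, c.weights * np.outer(survive, survive))


def generate_behavior(
    fi_standardized,
    cfg: SyntheticConfig,
    rng=None,
    damage_standardized=None,
    q_standardized=None,
) -> pd.DataFrame:
    """Behavior table (wab_aq + four subscores) from standardized predictors.

    score = clip(beta0 + beta_fi*fi_z + beta_damage*dmg_z + beta_q*q_z
                 + noise, 0, 100).
    Subscores share a latent severity factor (loading
    ``subscore_latent_loading``) so they correlate positively with each
    other beyond what the fragmentation signal alone induces.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    fi_z = np.asarray(fi_standardized, dtype=float)
    n = fi_z.shape[0]
    zeros = np.zeros(n)
    dmg_z = zeros if damage_standardized is None else np.asarray(damage_standardized)
    q_z = zeros if q_standardized is None else np.asarray(q_standardized)
    latent = (
        cfg.behavior_beta0
        + cfg.behavior_beta_fi * fi_z
        + cfg.behavior_beta_damage * dmg_z
        + cfg.behavior_beta_q * q_z
    )
    sd = cfg.behavior_noise_sd
    table = {"wab_aq": np.clip(latent + rng.normal(0.0, sd, n), 0.0, 100.0)}
    lam = cfg.subscore_latent_loading
    shared = rng.normal(0.0, sd, n)
    for name in SUBSCORE_NAMES:
        eps = rng.normal(0.0, sd, n)
        noise = lam * shared + np.sqrt(max(0.0, 1.0 - lam**2)) * eps
        table[name] = np.clip(latent + noise, 0.0, 100.0)
    return pd.DataFrame(table)


def _subject_rng(seed: int, subject_index: int, purpose: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=[seed, subject_index, purpose])
    )


def generate_cohort(
    cfg: SyntheticConfig, network_ground_truth: bool | None = None
) -> CohortData:
    """Generate a full synthetic cohort with ground truth.

    Per subject: healthy left and right hemispheres from the same block
    model (independent draws), weak homotopic interhemispheric edges, a
    contiguous lesion applied to the left hemisphere only, damage-derived
    covariates, and behavior scores from the internal (ground-truth)
    fragmentation index.

    ``network_ground_truth`` controls whether the generator runs its own
    consensus detection per hemisphere to obtain the internal FI/Q values
    (``fi_n_runs`` optimizations each).  Default: only when a behavior
    coefficient actually consumes them (beta_fi or beta_q nonzero).
    """
    if network_ground_truth is None:
        network_ground_truth = (
            cfg.behavior_beta_fi != 0.0 or cfg.behavior_beta_q != 0.0
        )
    n = cfg.n_regions_per_hemisphere
    if n == 57:
        parc = default_parcellation()
    else:
        parc = make_parcellation(n)
    left_ids = tuple(parc.region_ids[:n])
    right_ids = tuple(parc.region_ids[n:])
    all_ids = tuple(parc.region_ids)

    healthy_w = []
    lesioned_w = []
    damages = []
    gt_subjects = []
    for s in range(cfg.n_subjects):
        rng_net = _subject_rng(cfg.seed, s, 0)
        rng_les = _subject_rng(cfg.seed, s, 1)
        wl = _block_matrix(cfg, rng_net)
        wr = _block_matrix(cfg, rng_net)
        whole = np.zeros((2 * n, 2 * n))
        whole[:n, :n] = wl
        whole[n:, n:] = wr
        # weak homotopic commissural edges keep the whole network connected
        if cfg.w_inter > 0:
            inter = np.clip(
                rng_net.normal(
                    cfg.w_inter, cfg.weight_noise_cv * cfg.w_inter, n
                ),
                0.0,
                None,
            )
            whole[np.arange(n), np.arange(n) + n] = inter
            whole[np.arange(n) + n, np.arange(n)] = inter
        damage = generate_damage_profile(cfg, rng_les, region_ids=left_ids)
        d = np.zeros(2 * n)
        for rid, frac in damage.items():
            d[all_ids.index(rid)] = frac
        survive = 1.0 - d
        lesioned = whole * np.outer(survive, survive)
        healthy_w.append(whole)
        lesioned_w.append(lesioned)
        damages.append(damage)
        gt_subjects.append(
            {
                "lesion_extent": len(damage) / n,
                "n_damaged_regions": len(damage),
                "mean_severity": (
                    float(np.mean(list(damage.values()))) if damage else 0.0
                ),
            }
        )

    # internal network ground truth (generator-side consensus detection)
    fi = np.zeros(cfg.n_subjects)
    q_left = np.full(cfg.n_subjects, np.nan)
    if network_ground_truth:
        for s in range(cfg.n_subjects):
            rng_gt = _subject_rng(cfg.seed, s, 2)
            wl = lesioned_w[s][:n, :n]
            wr = lesioned_w[s][n:, n:]
            aff_l = consensus_affiliation(
                wl, n_runs=cfg.fi_n_runs, gamma=cfg.gamma, rng=rng_gt
            )
            aff_r = consensus_affiliation(
                wr, n_runs=cfg.fi_n_runs, gamma=cfg.gamma, rng=rng_gt
            )
            c_l = affiliation_index(aff_l)
            c_r = affiliation_index(aff_r)
            frag = fragmentation_index(c_r, c_l)
            fi[s] = frag.fi
            q_left[s] = aff_l.Q_best
            gt_subjects[s].update(
                {
                    "fi": frag.fi,
                    "c_left": c_l,
                    "c_right": c_r,
                    "q_left": aff_l.Q_best,
                    "q_right": aff_r.Q_best,
                }
            )

    def standardize(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    grey_total = np.array(
        [sum(dm.values()) / (2 * n) for dm in damages]
    )
    fi_z = standardize(fi)
    q_z = standardize(np.nan_to_num(q_left, nan=0.0))
    dmg_z = standardize(grey_total)
    rng_beh = np.random.default_rng(np.random.SeedSequence(entropy=[cfg.seed, 10**6]))
    behavior = generate_behavior(
        fi_z, cfg, rng_beh, damage_standardized=dmg_z, q_standardized=q_z
    )

    subjects = []
    for s in range(cfg.n_subjects):
        sid = f"S{s + 1:03d}"
        conn = Connectome(all_ids, lesioned_w[s])
        # white-matter damage proxy: strength-weighted mean damage, since
        # damage to well-connected regions destroys more connective tissue
        strength = healthy_w[s].sum(axis=1)
        d = np.array([damages[s].get(rid, 0.0) for rid in all_ids])
        white_total = float((d * strength).sum() / strength.sum())
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                wab_aq=float(behavior.loc[s, "wab_aq"]),
                subscores={k: float(behavior.loc[s, k]) for k in SUBSCORE_NAMES},
                damage=damages[s],
                grey_damage_total=float(grey_total[s]),
                white_damage_total=white_total,
                lesion_volume_cm3=float(sum(damages[s].values()) * cfg.region_volume_cm3),
                connectome=conn,
            )
        )
        gt_subjects[s]["subject_id"] = sid

    ground_truth = {
        "generator": "connfrag.simulate.generate_cohort",
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "coefficients": {
            "beta0": cfg.behavior_beta0,
            "beta_fi": cfg.behavior_beta_fi,
            "beta_damage": cfg.behavior_beta_damage,
            "beta_q": cfg.behavior_beta_q,
            "noise_sd": cfg.behavior_noise_sd,
        },
        "network_ground_truth": bool(network_ground_truth),
        "subjects": {g["subject_id"]: g for g in gt_subjects},
    }
    return CohortData(parcellation=parc, subjects=subjects, ground_truth=ground_truth)


def generate_planted_pair_cohort(
    cfg: SyntheticConfig,
    pair_effect: float = 20.0,
    noise_sd: float = 10.0,
    co_assignment_prob: float = 0.5,
    beta0: float = 60.0,
) -> CohortData:
    """Cohort with a single region pair whose co-assignment carries a score
    bonus — the positive control for the pairwise co-membership test.

    The last two left-hemisphere regions form a detached dyad: connected to
    each other (weight ``w_in``) and to nothing else.  With probability
    ``co_assignment_prob`` a subject keeps the dyad edge (the pair is then
    always co-assigned, affiliation entry 1) and scores ``pair_effect``
    higher on average; otherwise the edge is severed and the two regions
    fall into singleton modules.  No lesion damage is applied, so every
    subject is eligible for every pair.
    """
    n = cfg.n_regions_per_hemisphere
    if n < 2 * cfg.n_modules_healthy + 2:
        raise ValueError("need two spare regions for the planted dyad")
    parc = default_parcellation() if n == 57 else make_parcellation(n)
    all_ids = tuple(parc.region_ids)
    block_cfg = cfg.replace(n_regions_per_hemisphere=n - 2)
    subjects = []
    intact_flags = []
    rng_beh = np.random.default_rng(np.random.SeedSequence(entropy=[cfg.seed, 10**6 + 1]))
    for s in range(cfg.n_subjects):
        rng_net = _subject_rng(cfg.seed, s, 3)
        core = _block_matrix(block_cfg, rng_net)
        wl = np.zeros((n, n))
        wl[: n - 2, : n - 2] = core
        intact = bool(rng_net.random() < co_assignment_prob)
        if intact:
            w_dyad = max(
                0.0, rng_net.normal(cfg.w_in, cfg.weight_noise_cv * cfg.w_in)
            )
            wl[n - 2, n - 1] = wl[n - 1, n - 2] = w_dyad
        wr = _block_matrix(cfg, rng_net)
        whole = np.zeros((2 * n, 2 * n))
        whole[:n, :n] = wl
        whole[n:, n:] = wr
        score = float(
            np.clip(
                beta0 + pair_effect * intact + rng_beh.normal(0.0, noise_sd),
                0.0,
                100.0,
            )
        )
        subjects.append(
            SubjectRecord(
                subject_id=f"S{s + 1:03d}",
                wab_aq=score,
                subscores={k: score for k in SUBSCORE_NAMES},
                damage={},
                grey_damage_total=0.0,
                white_damage_total=0.0,
                lesion_volume_cm3=0.0,
                connectome=Connectome(all_ids, whole),
            )
        )
        intact_flags.append(intact)
    left_ids = parc.region_ids[:n]
    ground_truth = {
        "generator": "connfrag.simulate.generate_planted_pair_cohort",
        "seed": cfg.seed,
        "planted_pair": [left_ids[n - 2], left_ids[n - 1]],
        "pair_effect": pair_effect,
        "noise_sd": noise_sd,
        "co_assigned": {
            s.subject_id: bool(f) for s, f in zip(subjects, intact_flags)
        },
    }
    return CohortData(parcellation=parc, subjects=subjects, ground_truth=ground_truth)
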