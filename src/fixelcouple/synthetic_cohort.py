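"""Seeded synthetic cohorts with planted structure-function coupling.

The generator emulates the statistical structure the coupling analysis
assumes -- it does not simulate BOLD series, tractography or fixel images.
Simulation starts at the connectome level:

* one cohort-level fixel-SC edge mask (edges derive from a single template
  tractogram, so every subject shares the same fixel-SC skeleton; 5,922 of
  the 7,021 possible edges at the default 119-node scale);
* per-subject streamline-SC masks (per-subject tractography yields denser,
  variable masks; ~0.83 mean density with binomial jitter);
* per-edge log-normal fiber density (FD) and fiber-bundle cross-section
  (FbC) values around cohort edge profiles, with FDC = FD x FbC at the
  fixel-value level; every SC edge weight is the average fixel value
  multiplied by the edge's streamline count;
* signed, dense FC built from the subject's own standardized SC profile at
  mixing weight ``profile_rho`` plus a shared edge baseline and noise, so
  the expected subject-overall coupling equals ``profile_rho`` exactly;
* group-specific slopes on designated "planted" edges, driving edge-wise
  and node-wise group differences with known sign;
* cognition (MMSE and four RAVLT scores) driven by a latent memory factor
  that is shifted by group and by the subject's DMN nodal coupling.

All planted parameters are echoed in ``Cohort.ground_truth`` so that every
downstream estimator can be checked for parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .connectome_model import (
    GROUPS,
    RAVLT_SCORES,
    AtlasDefinition,
    ConnectomeMatrix,
    SubjectRecord,
    devectorize,
    EdgeVector,
    write_connectome,
)
from . import coupling_core

#: Yeo-7 network names; the Default network carries the DMN flag.
CORTICAL_NETWORKS = (
    "Vis",
    "SomMot",
    "DorsAttn",
    "SalVentAttn",
    "Limbic",
    "Cont",
    "Default",
)
#: Cortical allocation at the reference 119-node scale (100 cortical + 19
#: subcortical); Default holds the 24 DMN nodes.
_CANONICAL_SIZES = {
    "Vis": 15,
    "SomMot": 14,
    "DorsAttn": 12,
    "SalVentAttn": 12,
    "Limbic": 10,
    "Cont": 13,
    "Default": 24,
    "subcortical": 19,
}


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the reference cohort: 225 CN / 142 MCI / 25 AD
    participants, a 119-node atlas with 24 DMN nodes, 5,922 fixel-SC edges
    of 7,021 possible, ~0.83 mean per-subject streamline-SC density, and a
    planted whole-connectome subject coupling of 0.24 in every group.
    """

    n_per_group: dict = field(
        default_factory=lambda: {"CN": 225, "MCI": 142, "AD": 25}
    )
    n_nodes: int = 119
    dmn_size: int = 24
    #: Undirected fixel-SC edge density (shared cohort mask).
    fixel_edge_density: float = 5922 / 7021
    #: Mean per-subject undirected streamline-SC density (binomial jitter).
    streamline_edge_density: float = 5838 / 7021
    #: Within-subject SC-FC profile correlation per group.
    profile_rho: dict = field(
        default_factory=lambda: {"CN": 0.24, "MCI": 0.24, "AD": 0.24}
    )
    #: Number of planted edges with group-specific coupling slopes.
    n_planted_edges: int = 0
    #: Nodes whose entire incident edge set is planted (node-level effects).
    n_planted_nodes: int = 0
    #: Group -> extra FC slope on planted edges (in FC-noise SD units).
    edge_slope: dict = field(
        default_factory=lambda: {"CN": 0.0, "MCI": 0.0, "AD": 0.0}
    )
    #: Share of FC noise variance held by the shared edge baseline.
    fc_baseline_share: float = 0.5
    #: Log-scale SD of subject fixel values around the edge profile.
    sc_sigma: float = 0.30
    #: Standardized effect of DMN nodal coupling on the latent memory factor.
    cognition_effect: float = 0.35
    #: Group shifts of the latent memory factor (CN > MCI > AD).
    group_cognition_shift: dict = field(
        default_factory=lambda: {"CN": 0.5, "MCI": -0.4, "AD": -1.6}
    )
    #: One-factor loadings of the four RAVLT indicators.
    loadings: tuple = (0.9, 0.9, 0.8, 0.7)
    #: SD of the latent memory factor's residual noise.
    cognition_noise: float = 1.0
    #: Per-group probability of missing RAVLT (emulates 349/392 completers).
    ravlt_missing_rate: dict = field(
        default_factory=lambda: {"CN": 22 / 225, "MCI": 15 / 142, "AD": 6 / 25}
    )
    mmse_missing_rate: float = 1 / 392
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.dmn_size < self.n_nodes):
            raise ValueError("dmn_size must be a strict subset of nodes")
        for d in (self.fixel_edge_density, self.streamline_edge_density):
            if not (0.0 < d <= 1.0):
                raise ValueError("edge densities must be in (0, 1]")

    @property
    def n_edges(self) -> int:
        return self.n_nodes * (self.n_nodes - 1) // 2


@dataclass
class Cohort:
    atlas: AtlasDefinition
    subjects: list
    ground_truth: dict

    def by_group(self, group: str) -> list:
        return [s for s in self.subjects if s.group == group]


def generate_atlas(cfg: GeneratorConfig) -> AtlasDefinition:
    """Deterministic atlas: 7 cortical networks + subcortical block.

    The Default network holds exactly ``dmn_size`` DMN-flagged nodes.  At
    the 119-node reference scale the allocation follows the canonical
    parcel counts; other sizes distribute non-DMN nodes round-robin.
    """
    sizes = {}
    if cfg.n_nodes == 119 and cfg.dmn_size == 24:
        sizes = dict(_CANONICAL_SIZES)
    else:
        sizes = {name: 0 for name in CORTICAL_NETWORKS}
        sizes["subcortical"] = 0
        sizes["Default"] = cfg.dmn_size
        others = [n for n in CORTICAL_NETWORKS if n != "Default"] + ["subcortical"]
        remaining = cfg.n_nodes - cfg.dmn_size
        for k in range(remaining):
            sizes[others[k % len(others)]] += 1
    labels, networks, is_dmn = [], [], []
    for name in list(CORTICAL_NETWORKS) + ["subcortical"]:
        for k in range(sizes.get(name, 0)):
            labels.append(f"{name}_{k + 1}")
            networks.append(name)
            is_dmn.append(name == "Default")
    return AtlasDefinition(
        labels=tuple(labels), network=tuple(networks), is_dmn=tuple(is_dmn)
    )


class CohortGenerator:
    """Holds the cohort-level template (masks, edge profiles, planted set).

    All randomness flows from ``cfg.seed`` through one ``numpy`` Generator,
    so a fixed config is bit-reproducible.
    """

    def __init__(self, cfg: GeneratorConfig):
        self.cfg = cfg
        self.atlas = generate_atlas(cfg)
        self.rng = np.random.default_rng(cfg.seed)
        self._build_template()

    # -- cohort-level template ------------------------------------------

    def _build_template(self):
        cfg = self.cfg
        m = cfg.n_edges
        rng = self.rng
        n_fixel = int(round(cfg.fixel_edge_density * m))
        fixel_idx = rng.choice(m, size=n_fixel, replace=False)
        self.fixel_mask = np.zeros(m, dtype=bool)
        self.fixel_mask[fixel_idx] = True
        # per-edge cohort profiles (log scale); FD ~ 0.3-0.8, FbC ~ 1.0
        self.mu_log_fd = rng.normal(np.log(0.5), 0.35, size=m)
        self.mu_log_fbc = rng.normal(0.0, 0.30, size=m)
        # template streamline counts weight the fixel metrics
        self.template_streamlines = 1 + rng.poisson(
            np.exp(rng.normal(np.log(40.0), 1.0, size=m))
        )
        # per-edge mean streamline counts for the subject-level tractography
        self.streamline_mu = np.exp(rng.normal(np.log(30.0), 1.0, size=m))
        # shared FC edge baseline (unit variance)
        self.fc_baseline = rng.standard_normal(m)
        # analytic cross-subject moments of the FD edge weights (log-normal
        # fixel value x fixed template count); used to standardize the
        # planted-slope term across subjects
        sig2 = self.cfg.sc_sigma**2
        self.fd_edge_mean = self.template_streamlines * np.exp(
            self.mu_log_fd + sig2 / 2.0
        )
        self.fd_edge_sd = self.fd_edge_mean * np.sqrt(np.expm1(sig2))
        # planted edges: incident edges of planted nodes first, then extras
        planted = np.zeros(m, dtype=bool)
        iu, ju = np.triu_indices(cfg.n_nodes, k=1)
        planted_nodes = np.array([], dtype=int)
        if cfg.n_planted_nodes > 0:
            planted_nodes = rng.choice(
                cfg.n_nodes, size=cfg.n_planted_nodes, replace=False
            )
            incident = np.isin(iu, planted_nodes) | np.isin(ju, planted_nodes)
            planted |= incident & self.fixel_mask
        if cfg.n_planted_edges > 0:
            candidates = np.flatnonzero(self.fixel_mask & ~planted)
            extra = rng.choice(
                candidates, size=cfg.n_planted_edges, replace=False
            )
            planted[extra] = True
        self.planted_edges = planted
        self.planted_nodes = planted_nodes

    # -- per-subject draws ----------------------------------------------

    def _draw_fixel_values(self):
        """Per-edge subject fixel values: FD, FbC and FDC = FD x FbC."""
        cfg = self.cfg
        m = cfg.n_edges
        fd = np.exp(self.mu_log_fd + cfg.sc_sigma * self.rng.standard_normal(m))
        fbc = np.exp(self.mu_log_fbc + cfg.sc_sigma * self.rng.standard_normal(m))
        return {"FD": fd, "FbC": fbc, "FDC": fd * fbc}

    def generate_sc(self, group: str) -> dict:
        """One subject's four SC matrices (modality -> ConnectomeMatrix).

        Fixel modalities share the cohort mask and are weighted by the
        template streamline counts (average fixel value x count, the fixel
        edge-weight construction).  Streamline SC gets its own binomial
        mask and per-edge dispersed counts.
        """
        cfg = self.cfg
        m = cfg.n_edges
        fixel = self._draw_fixel_values()
        counts = self.template_streamlines
        vectors = {
            "FD": fixel["FD"] * counts,
            "logFbC": np.log(fixel["FbC"]) * counts,
            "FDC": fixel["FDC"] * counts,
        }
        out = {}
        for modality, values in vectors.items():
            out[modality] = devectorize(
                EdgeVector(modality, values, self.fixel_mask.copy(), cfg.n_nodes)
            )
        streamline_mask = (
            self.rng.random(m) < cfg.streamline_edge_density
        )
        streamline_counts = 1.0 + self.rng.poisson(self.streamline_mu)
        out["streamline"] = devectorize(
            EdgeVector(
                "streamline",
                np.where(streamline_mask, streamline_counts, np.nan),
                streamline_mask,
                cfg.n_nodes,
            )
        )
        return out

    def generate_fc(self, sc: Mapping, group: str) -> ConnectomeMatrix:
        """Signed, dense FC with planted coupling to the subject's fixel SC.

        FC_e = rho * z(SC_e) + slope_g * w(SC_e) [planted edges]
               + sqrt(1 - rho^2) * (w_b * baseline_e + w_n * eps_e)

        where z standardizes the subject's FD edge weights over present
        edges (within-subject; drives subject-overall coupling), w
        standardizes each edge weight across subjects using the analytic
        template moments (drives edge-wise coupling on planted edges),
        ``baseline_e`` is a cohort-shared edge profile and eps is
        idiosyncratic noise.  Because z has unit variance and the noise
        term has variance 1 - rho^2, the expected within-subject Pearson
        correlation over SC-present edges is exactly ``rho``.  Edges with
        no fixel-SC support still receive FC (FC is dense).
        """
        cfg = self.cfg
        m = cfg.n_edges
        rho = float(cfg.profile_rho[group])
        slope = float(cfg.edge_slope.get(group, 0.0))
        sc_vec = sc["FD"].weights[np.triu_indices(cfg.n_nodes, k=1)]
        present = self.fixel_mask
        z = np.zeros(m)
        on = sc_vec[present]
        z[present] = (on - on.mean()) / on.std()
        w_b = np.sqrt(cfg.fc_baseline_share)
        w_n = np.sqrt(1.0 - cfg.fc_baseline_share)
        noise = w_b * self.fc_baseline + w_n * self.rng.standard_normal(m)
        fc = rho * z + np.sqrt(max(0.0, 1.0 - rho**2)) * noise
        w = np.where(
            present, (np.nan_to_num(sc_vec) - self.fd_edge_mean) / self.fd_edge_sd, 0.0
        )
        fc = fc + slope * w * self.planted_edges
        # keep the Fisher-Z scale realistic (|FC| mostly < 1.5)
        fc = 0.4 * fc
        return devectorize(
            EdgeVector("FC", fc, np.ones(m, dtype=bool), cfg.n_nodes)
        )

    # -- covariates and cognition ---------------------------------------

    _AGE = {"CN": 72.3, "MCI": 73.9, "AD": 74.7}
    _P_FEMALE = {"CN": 137 / 225, "MCI": 63 / 142, "AD": 7 / 25}

    def _draw_covariates(self, group: str):
        age = float(np.clip(self.rng.normal(self._AGE[group], 8.0), 55.0, 95.0))
        sex = "F" if self.rng.random() < self._P_FEMALE[group] else "M"
        icv = float(
            self.rng.normal(1.5e6 * (1.08 if sex == "M" else 1.0), 1.2e5)
        )
        return age, sex, icv

    def generate_cognition(self, subjects: Sequence[SubjectRecord]) -> None:
        """Fill mmse/ravlt in place from group and DMN nodal coupling.

        Latent memory M_i = shift(group) + effect * z(DMN nodal coupling)
        + noise; the four RAVLT indicators load on standardized M with the
        configured loadings; MMSE is an integer-rounded linear map of
        standardized M clipped to 0-30.
        """
        cfg = self.cfg
        dmn = self.atlas.dmn_nodes
        node_coupling = np.empty(len(subjects))
        for i, s in enumerate(subjects):
            sc_s = coupling_core.node_strength(s.matrices["FD"])[dmn]
            fc_s = coupling_core.node_strength(s.matrices["FC"])[dmn]
            ok = np.isfinite(sc_s) & np.isfinite(fc_s)
            node_coupling[i] = (
                coupling_core._pearson(sc_s[ok], fc_s[ok]) if ok.sum() >= 3
                else np.nan
            )
        zc = (node_coupling - np.nanmean(node_coupling)) / np.nanstd(node_coupling)
        zc = np.nan_to_num(zc)
        shifts = np.array(
            [cfg.group_cognition_shift[s.group] for s in subjects]
        )
        latent = (
            shifts
            + cfg.cognition_effect * zc
            + cfg.cognition_noise * self.rng.standard_normal(len(subjects))
        )
        mz = (latent - latent.mean()) / latent.std()
        loadings = np.asarray(cfg.loadings, float)
        resid_sd = np.sqrt(1.0 - loadings**2)
        # plausible RAVLT scales (location, spread, ceiling)
        scales = {
            "learning": (5.0, 1.8, 14.0),
            "immediate": (35.0, 11.0, 75.0),
            "delay30": (7.0, 3.4, 15.0),
            "recognition": (11.0, 2.6, 15.0),
        }
        self._latent_memory = mz  # exposed via ground truth
        for i, subj in enumerate(subjects):
            ravlt = {}
            if self.rng.random() >= cfg.ravlt_missing_rate[subj.group]:
                for k, score in enumerate(RAVLT_SCORES):
                    ind = loadings[k] * mz[i] + resid_sd[k] * self.rng.standard_normal()
                    loc, spread, top = scales[score]
                    ravlt[score] = float(np.clip(loc + spread * ind, 0.0, top))
                subj.ravlt = ravlt
            else:
                subj.ravlt = None
            if self.rng.random() >= cfg.mmse_missing_rate:
                subj.mmse = float(np.clip(round(26.5 + 2.5 * mz[i]), 0, 30))
            else:
                subj.mmse = None

    # -- full cohort -----------------------------------------------------

    def generate(self) -> Cohort:
        subjects = []
        idx = 0
        for group in GROUPS:
            for _ in range(self.cfg.n_per_group.get(group, 0)):
                idx += 1
                age, sex, icv = self._draw_covariates(group)
                sc = self.generate_sc(group)
                fc = self.generate_fc(sc, group)
                matrices = dict(sc)
                matrices["FC"] = fc
                subjects.append(
                    SubjectRecord(
                        subject_id=f"sub-{idx:04d}",
                        group=group,
                        age=age,
                        sex=sex,
                        icv=icv,
                        matrices=matrices,
                    )
                )
        self.generate_cognition(subjects)
        truth = {
            "seed": self.cfg.seed,
            "profile_rho": dict(self.cfg.profile_rho),
            "edge_slope": dict(self.cfg.edge_slope),
            "planted_edges": np.flatnonzero(self.planted_edges).tolist(),
            "planted_nodes": self.planted_nodes.tolist(),
            "cognition_effect": self.cfg.cognition_effect,
            "group_cognition_shift": dict(self.cfg.group_cognition_shift),
            "loadings": list(self.cfg.loadings),
            "fixel_edge_count": int(self.fixel_mask.sum()),
            "latent_memory": self._latent_memory.tolist(),
            "note": (
                "log-normal edge-weight forms are a modeling choice, "
                "not a claim about the source cohort's distributions"
            ),
        }
        return Cohort(atlas=self.atlas, subjects=subjects, ground_truth=truth)


def generate_cohort(cfg: GeneratorConfig | None = None, **overrides) -> Cohort:
    """Generate a full synthetic cohort (convenience wrapper)."""
    if cfg is None:
        cfg = GeneratorConfig(**overrides)
    elif overrides:
        cfg = dataclass_replace(cfg, **overrides)
    return CohortGenerator(cfg).generate()


def dataclass_replace(cfg: GeneratorConfig, **overrides) -> GeneratorConfig:
    import dataclasses

    return dataclasses.replace(cfg, **overrides)


def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Write manifest + atlas + per-subject TSV connectomes + ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.atlas.to_tsv(out / "atlas.tsv")
    rows = []
    for s in cohort.subjects:
        row = {
            "subject_id": s.subject_id,
            "group": s.group,
            "age": s.age,
            "sex": s.sex,
            "icv": s.icv,
            "mmse": "" if s.mmse is None else s.mmse,
        }
        for score in RAVLT_SCORES:
            row[f"ravlt_{score}"] = (
                "" if s.ravlt is None else s.ravlt.get(score, "")
            )
        sub_dir = out / s.subject_id
        sub_dir.mkdir(exist_ok=True)
        for modality, matrix in s.matrices.items():
            rel = f"{s.subject_id}/{modality}.tsv"
            write_connectome(matrix, out / rel, labels=cohort.atlas.labels)
            row[f"path_{modality}"] = rel
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "manifest.tsv", sep="\t", index=False)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(cohort.ground_truth, fh, indent=1)
    return out


def cohort_dataframe(cohort: Cohort) -> pd.DataFrame:
    """Covariate/cognition table with one row per subject."""
    rows = []
    for s in cohort.subjects:
        row = {
            "subject_id": s.subject_id,
            "group": s.group,
            "age": s.age,
            "sex": s.sex,
            "icv": s.icv,
            "mmse": np.nan if s.mmse is None else s.mmse,
        }
        for score in RAVLT_SCORES:
            row[f"ravlt_{score}"] = (
                np.nan if s.ravlt is None else s.ravlt.get(score, np.nan)
            )
        rows.append(row)
    return pd.DataFrame(rows)
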