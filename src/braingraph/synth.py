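"""Synthetic fiber-bundle cohorts.

The generator emulates the *shape* of an HCP-style tractography cohort — two
sex-labelled groups (52 + 44 subjects by default), several parcellation
resolutions with left/right/midline node labels, and per-ROI-pair fiber
count / mean length / mean FA summaries — with a simple stochastic-blockmodel
generative law:

* edges are sampled independently, with probability ``p_intra`` within a
  hemisphere and ``p_inter`` between hemispheres (midline "other" nodes
  count as inter for every pair they touch);
* per-subject density heterogeneity is a log-normal multiplier on the edge
  probabilities (``sigma_subject``);
* fiber counts are rounded log-normal (>= 1), lengths log-normal (mm) and
  FA values Beta-distributed, clipped into (0, 1];
* group A (sex label F) carries multiplicative effect sizes ``delta_p``
  (edge probability), ``delta_fiber`` (counts) and ``delta_fa`` (FA); with
  all deltas at 1 the two groups are exchangeable.

Subject IDs are 6-digit strings so the digit-sum-parity split used by the
statistics pipeline is well defined and near-balanced.  Everything is
deterministic given the root seed: per-(subject, resolution) streams are
derived with ``numpy.random.SeedSequence`` so cohorts are reproducible under
any generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .graph_core import (
    FIBER_TABLE_COLUMNS,
    InputError,
    Parcellation,
    read_fiber_table,
    read_parcellation,
    write_fiber_table,
    write_parcellation,
)

__all__ = [
    "SyntheticCohortConfig",
    "SubjectData",
    "Cohort",
    "default_hemisphere_sizes",
    "make_parcellation",
    "generate_subject",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

STANDARD_RESOLUTIONS = (83, 129, 234, 463, 1015)


def default_hemisphere_sizes(resolution: int) -> tuple[int, int, int]:
    """(left, right, other) node counts: equal hemispheres, remainder midline."""
    other = resolution % 2
    half = (resolution - other) // 2
    return half, half, other


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the emulated cohort: 52 group-A (F) and 44 group-B (M)
    subjects at the five standard resolutions.  Distribution parameters are
    the generator's own realistic choices (log-normal counts with median
    ~7 fibers, log-normal lengths with median ~30 mm, Beta(8,12) FA with
    mean 0.4, 2% per-subject density heterogeneity).
    """

    n_group_a: int = 52
    n_group_b: int = 44
    resolutions: tuple[int, ...] = STANDARD_RESOLUTIONS
    hemisphere_sizes: Mapping[int, tuple[int, int, int]] | None = None
    p_intra: float = 0.30
    p_inter: float = 0.10
    mu_log_fiber: float = 2.0
    sigma_log_fiber: float = 1.0
    mu_log_length: float = 3.4
    sigma_log_length: float = 0.5
    fa_alpha: float = 8.0
    fa_beta: float = 12.0
    sigma_subject: float = 0.02
    delta_p: float = 1.0
    delta_fiber: float = 1.0
    delta_fa: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.p_intra <= 1.0 and 0.0 <= self.p_inter <= 1.0):
            raise InputError("edge probabilities must lie in (0, 1]")
        if self.n_group_a < 1 or self.n_group_b < 1:
            raise InputError("both groups need at least one subject")
        for d in (self.delta_p, self.delta_fiber, self.delta_fa):
            if d <= 0:
                raise InputError("effect multipliers must be positive")

    def sizes_for(self, resolution: int) -> tuple[int, int, int]:
        if self.hemisphere_sizes and resolution in self.hemisphere_sizes:
            left, right, other = self.hemisphere_sizes[resolution]
            if left + right + other != resolution:
                raise InputError(
                    f"hemisphere sizes {left}+{right}+{other} != {resolution}"
                )
            return left, right, other
        return default_hemisphere_sizes(resolution)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticCohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "resolutions" in raw:
            raw["resolutions"] = tuple(int(r) for r in raw["resolutions"])
        if "hemisphere_sizes" in raw and raw["hemisphere_sizes"] is not None:
            raw["hemisphere_sizes"] = {
                int(k): tuple(int(x) for x in v)
                for k, v in raw["hemisphere_sizes"].items()
            }
        return cls(**raw)


@dataclass
class SubjectData:
    subject_id: str
    sex: str  # "F" | "M"
    fiber_tables: dict[int, pd.DataFrame]  # resolution -> table


@dataclass
class Cohort:
    subjects: list[SubjectData]
    parcellations: dict[int, Parcellation]
    config: SyntheticCohortConfig | None = None

    @property
    def resolutions(self) -> tuple[int, ...]:
        return tuple(sorted(self.parcellations))

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.subjects],
                "sex": [s.sex for s in self.subjects],
            }
        )


def make_parcellation(resolution: int,
                      sizes: tuple[int, int, int] | None = None) -> Parcellation:
    """Synthetic parcellation: zero-padded L*/R*/O* node names."""
    left, right, other = sizes or default_hemisphere_sizes(resolution)
    if left + right + other != resolution:
        raise InputError("hemisphere sizes must sum to the resolution")
    width = len(str(max(left, right, other, 1)))
    nodes, hemi = [], {}
    for prefix, count, label in (
        ("L", left, "left"), ("O", other, "other"), ("R", right, "right"),
    ):
        for i in range(count):
            name = f"{prefix}{i:0{width}d}"
            nodes.append(name)
            hemi[name] = label
    return Parcellation(tuple(sorted(nodes)), hemi)


# cache of upper-triangle pair indices and intra-hemisphere masks per
# (resolution, sizes): pair enumeration dominates generation cost otherwise
_PAIR_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _pairs(parcellation: Parcellation):
    key = (parcellation.nodes,)
    if key not in _PAIR_CACHE:
        n = parcellation.resolution
        iu, iv = np.triu_indices(n, k=1)
        labels = np.array(
            [parcellation.hemisphere[v] for v in parcellation.nodes]
        )
        intra = (labels[iu] == labels[iv]) & (labels[iu] != "other")
        _PAIR_CACHE[key] = (iu, iv, intra)
    return _PAIR_CACHE[key]


def subject_id_for(index: int) -> str:
    """6-digit HCP-like subject ID for the cohort-wide subject index."""
    return str(100_000 + index)


def generate_subject(
    config: SyntheticCohortConfig,
    subject_index: int,
    group: str,
    resolution: int,
    parcellation: Parcellation | None = None,
) -> pd.DataFrame:
    """One subject's fiber table at one resolution.

    Deterministic given ``(config.seed, subject_index, resolution)``; the
    group enters only through the effect multipliers, so with all deltas at
    1 relabelling groups leaves every table unchanged (exchangeability).
    """
    if group not in ("A", "B"):
        raise InputError("group must be 'A' or 'B'")
    parcellation = parcellation or make_parcellation(
        resolution, config.sizes_for(resolution)
    )
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, subject_index, resolution])
    )
    iu, iv, intra = _pairs(parcellation)
    subj_mult = float(
        np.exp(rng.normal(0.0, config.sigma_subject))
    )
    probs = np.where(intra, config.p_intra, config.p_inter) * subj_mult
    if group == "A":
        probs = probs * config.delta_p
    probs = np.clip(probs, 0.0, 1.0)
    edge = rng.random(len(probs)) < probs
    eu, ev = iu[edge], iv[edge]
    m = len(eu)
    counts = rng.lognormal(config.mu_log_fiber, config.sigma_log_fiber, m)
    if group == "A":
        counts = counts * config.delta_fiber
    counts = np.maximum(1, np.rint(counts)).astype(int)
    lengths = rng.lognormal(config.mu_log_length, config.sigma_log_length, m)
    fa = rng.beta(config.fa_alpha, config.fa_beta, m)
    if group == "A":
        fa = fa * config.delta_fa
    fa = np.clip(fa, 1e-9, 1.0)
    nodes = np.asarray(parcellation.nodes)
    return pd.DataFrame(
        {
            "node_u": nodes[eu],
            "node_v": nodes[ev],
            "fiber_count": counts,
            "mean_length": lengths,
            "mean_fa": fa,
        },
        columns=list(FIBER_TABLE_COLUMNS),
    )


def generate_cohort(config: SyntheticCohortConfig) -> Cohort:
    """The full in-memory cohort: group A first (sex F), then group B (M)."""
    parcellations = {
        r: make_parcellation(r, config.sizes_for(r)) for r in config.resolutions
    }
    subjects = []
    for index in range(config.n_group_a + config.n_group_b):
        group = "A" if index < config.n_group_a else "B"
        sex = "F" if group == "A" else "M"
        tables = {
            r: generate_subject(config, index, group, r, parcellations[r])
            for r in config.resolutions
        }
        subjects.append(SubjectData(subject_id_for(index), sex, tables))
    return Cohort(subjects, parcellations, config)


def write_cohort(cohort: Cohort, out_dir: str | Path,
                 overwrite: bool = False) -> Path:
    """Write fiber CSVs (one per subject per resolution), parcellation CSVs
    and a ``manifest.csv`` with subject IDs and sex labels."""
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.csv"
    if manifest_path.exists() and not overwrite:
        raise InputError(f"{manifest_path} exists; pass overwrite to replace")
    out_dir.mkdir(parents=True, exist_ok=True)
    for resolution, parcellation in cohort.parcellations.items():
        write_parcellation(parcellation, out_dir / f"parcellation_{resolution}.csv")
    for subject in cohort.subjects:
        for resolution, table in subject.fiber_tables.items():
            write_fiber_table(
                table, out_dir / f"fibers_{subject.subject_id}_{resolution}.csv"
            )
    manifest = cohort.manifest()
    manifest["resolutions"] = ";".join(str(r) for r in cohort.resolutions)
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def read_cohort(in_dir: str | Path) -> Cohort:
    """Load a cohort directory written by :func:`write_cohort`."""
    in_dir = Path(in_dir)
    manifest_path = in_dir / "manifest.csv"
    if not manifest_path.exists():
        raise InputError(f"no manifest.csv under {in_dir}")
    manifest = pd.read_csv(manifest_path, dtype={"subject_id": str})
    if manifest.empty:
        raise InputError(f"{manifest_path} lists no subjects")
    resolutions = sorted(
        {int(r) for r in str(manifest["resolutions"].iloc[0]).split(";")}
    )
    parcellations = {
        r: read_parcellation(in_dir / f"parcellation_{r}.csv") for r in resolutions
    }
    subjects = []
    missing = []
    for _, row in manifest.iterrows():
        tables = {}
        for r in resolutions:
            path = in_dir / f"fibers_{row['subject_id']}_{r}.csv"
            if not path.exists():
                missing.append((row["subject_id"], r))
                continue
            tables[r] = read_fiber_table(path)
        subjects.append(SubjectData(str(row["subject_id"]), row["sex"], tables))
    if missing:
        raise InputError(f"missing fiber tables: {missing[:10]}")
    return Cohort(subjects, parcellations)
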