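"""Synthetic methylation cohorts with nested two-level labels.

Real 450K reference cohorts pair each sample with a methylation subclass
(MC) nested inside a coarser methylation class family (MCF), show severe
class imbalance (some classes hold fewer than 10 samples), and carry
bounded, bimodal beta values.  This module emulates those features so the
whole SSL pipeline can be exercised without array data: each subclass owns
a set of informative probes set to a high methylation level against a low
baseline, subclasses within a family share part of that set (families are
coarser clusters), and per-sample values are beta-distributed around the
subclass archetype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "generate_cohort",
    "generate_probe_annotation",
    "inject_label_noise",
]

# beta values are clipped away from the exact 0/1 boundary so no feature is
# degenerate for downstream learners
_CLIP = 1e-6


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic methylation cohort.

    Parameters
    ----------
    n_families:
        Number of methylation class families (MCF).
    subclasses_per_family:
        Number of subclasses (MC) in each family; length ``n_families``.
    samples_per_subclass:
        Samples per subclass, one entry per subclass in family order.
        Values below 10 are allowed and model rare tumor classes.
    n_probes:
        Total probes on the simulated array.
    n_informative_per_subclass:
        Probes elevated to ``level_high`` for each subclass.
    level_low, level_high:
        Beta means of the unmethylated / methylated state (defaults 0.1,
        0.9, giving the bimodality typical of beta values).
    concentration:
        Pseudo-count of the beta noise distribution; larger means less
        noise.  ``inf`` yields noiseless samples equal to the archetype.
    background_sd:
        Spread of the per-probe baseline means of uninformative probes.
    family_share:
        Fraction of each subclass's informative probes drawn from a pool
        common to its family, making MCF structure coarser than MC.
    seed:
        Seed of the generator; identical spec+seed gives an identical
        cohort.
    """

    n_families: int
    subclasses_per_family: Sequence[int]
    samples_per_subclass: Sequence[int]
    n_probes: int
    n_informative_per_subclass: int
    level_low: float = 0.1
    level_high: float = 0.9
    concentration: float = 50.0
    background_sd: float = 0.05
    family_share: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.subclasses_per_family) != self.n_families:
            raise ValueError(
                "subclasses_per_family must have one entry per family "
                f"({len(self.subclasses_per_family)} != {self.n_families})"
            )
        n_sub = int(sum(self.subclasses_per_family))
        if len(self.samples_per_subclass) != n_sub:
            raise ValueError(
                "samples_per_subclass must have one entry per subclass "
                f"({len(self.samples_per_subclass)} != {n_sub})"
            )
        if any(n < 2 for n in self.samples_per_subclass):
            raise ValueError("every subclass needs >= 2 samples")
        if self.n_informative_per_subclass * n_sub > self.n_probes:
            raise ValueError(
                "n_informative_per_subclass * n_subclasses exceeds n_probes"
            )
        if not (0.0 <= self.level_low <= 1.0 and 0.0 <= self.level_high <= 1.0):
            raise ValueError("levels must lie in [0, 1]")
        if not self.concentration > 0:
            raise ValueError("concentration must be positive")
        if not (0.0 <= self.family_share <= 1.0):
            raise ValueError("family_share must lie in [0, 1]")

    @property
    def n_subclasses(self) -> int:
        return int(sum(self.subclasses_per_family))

    @property
    def n_samples(self) -> int:
        return int(sum(self.samples_per_subclass))


@dataclass
class SyntheticCohort:
    """A generated cohort: beta values, nested labels and ground truth."""

    beta: "pd.DataFrame"  # samples x probes, values in [0, 1]
    mc_labels: np.ndarray
    mcf_labels: np.ndarray
    informative_probes: Dict[str, np.ndarray]
    archetypes: "pd.DataFrame"  # subclass x probes mean methylation
    mc_to_mcf: Dict[str, str] = field(default_factory=dict)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.beta.index.to_numpy()

    @property
    def probe_ids(self) -> np.ndarray:
        return self.beta.columns.to_numpy()

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "mc": self.mc_labels, "mcf": self.mcf_labels}
        )


def _allocate_informative(spec: CohortSpec, rng: np.random.Generator):
    """Assign informative probe index sets, partially shared within families."""
    pool = rng.permutation(spec.n_probes)
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        out = pool[cursor : cursor + k]
        cursor += k
        return out

    n_inf = spec.n_informative_per_subclass
    n_shared = int(round(spec.family_share * n_inf))
    sets: Dict[str, np.ndarray] = {}
    mc_to_mcf: Dict[str, str] = {}
    mc_idx = 0
    for f, n_sub in enumerate(spec.subclasses_per_family):
        fam = f"f{f:02d}"
        shared = take(n_shared)
        for _ in range(n_sub):
            mc = f"mc{mc_idx:02d}"
            private = take(n_inf - n_shared)
            sets[mc] = np.sort(np.concatenate([shared, private]))
            mc_to_mcf[mc] = fam
            mc_idx += 1
    return sets, mc_to_mcf


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a methylation-like cohort from ``spec``.

    Each subclass archetype holds ``level_high`` at its informative probes,
    ``level_low`` at probes informative for any other subclass, and a
    per-probe baseline elsewhere.  Samples are drawn probe-wise from a beta
    distribution with mean equal to the archetype and the spec's common
    concentration; ``concentration=inf`` reproduces the archetype exactly.
    Deterministic for a fixed spec (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    inf_sets, mc_to_mcf = _allocate_informative(spec, rng)
    mcs = list(inf_sets)

    baseline = np.clip(
        rng.normal(0.5, spec.background_sd, size=spec.n_probes), 0.02, 0.98
    )
    informative_union = np.unique(np.concatenate(list(inf_sets.values()))) if mcs else []

    archetypes = np.tile(baseline, (len(mcs), 1))
    archetypes[:, informative_union] = spec.level_low
    for i, mc in enumerate(mcs):
        archetypes[i, inf_sets[mc]] = spec.level_high
    archetypes = np.clip(archetypes, _CLIP, 1.0 - _CLIP)

    n = spec.n_samples
    mc_labels = np.repeat(mcs, spec.samples_per_subclass)
    mcf_labels = np.array([mc_to_mcf[m] for m in mc_labels])

    mc_row = {mc: i for i, mc in enumerate(mcs)}
    means = archetypes[[mc_row[m] for m in mc_labels], :]
    if np.isinf(spec.concentration):
        values = means.copy()
    else:
        a = means * spec.concentration
        b = (1.0 - means) * spec.concentration
        values = rng.beta(a, b, size=(n, spec.n_probes))
    values = np.clip(values, _CLIP, 1.0 - _CLIP)

    sample_ids = [f"s{i:04d}" for i in range(n)]
    probe_ids = [f"cg{j:06d}" for j in range(spec.n_probes)]
    beta = pd.DataFrame(values, index=sample_ids, columns=probe_ids)
    arch = pd.DataFrame(archetypes, index=mcs, columns=probe_ids)
    return SyntheticCohort(
        beta=beta,
        mc_labels=mc_labels,
        mcf_labels=mcf_labels,
        informative_probes=inf_sets,
        archetypes=arch,
        mc_to_mcf=mc_to_mcf,
    )


def generate_probe_annotation(
    n_probes: int,
    frac_sex: float = 0.0,
    frac_snp: float = 0.0,
    frac_multimap: float = 0.0,
    frac_crossreactive: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Random probe-annotation table with the four removal flags.

    Flags mirror the standard 450K exclusion reasons: probes on sex
    chromosomes, probes with a common SNP within 5 bp of the CpG, probes
    multi-mapping on hg19, and cross-reactive probes.  Exactly
    ``round(frac * n_probes)`` probes receive each flag; flags are drawn
    independently and may overlap.  Deterministic per seed.
    """
    fracs = {
        "on_sex_chromosome": frac_sex,
        "snp_within_5bp": frac_snp,
        "multimap_hg19": frac_multimap,
        "cross_reactive": frac_crossreactive,
    }
    for name, frac in fracs.items():
        if not (0.0 <= frac <= 1.0):
            raise ValueError(f"{name} fraction must lie in [0, 1], got {frac}")
    rng = np.random.default_rng(seed)
    probe_ids = [f"cg{j:06d}" for j in range(n_probes)]
    table = pd.DataFrame({"probe_id": probe_ids}).set_index("probe_id")
    for name, frac in fracs.items():
        flags = np.zeros(n_probes, dtype=bool)
        k = int(round(frac * n_probes))
        if k:
            flags[rng.choice(n_probes, size=k, replace=False)] = True
        table[name] = flags
    return table.reset_index()


def inject_label_noise(labels, rate: float, seed: int = 0):
    """Flip ``round(rate * n)`` labels to a different class, uniformly.

    Returns the corrupted label vector and a boolean mask of flipped
    positions.  Used to probe the mislabel-editing behaviour of SETRED.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must lie in [0, 1)")
    labels = np.asarray(labels)
    classes = np.unique(labels)
    out = labels.copy()
    mask = np.zeros(labels.shape[0], dtype=bool)
    k = int(round(rate * labels.shape[0]))
    if k == 0:
        return out, mask
    if classes.size < 2:
        raise ValueError("label noise needs >= 2 distinct classes")
    rng = np.random.default_rng(seed)
    idx = rng.choice(labels.shape[0], size=k, replace=False)
    for i in idx:
        others = classes[classes != labels[i]]
        out[i] = rng.choice(others)
    mask[idx] = True
    return out, mask
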