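"""Beta-matrix container, probe filtering and SD feature selection.

The pipeline accepts a beta matrix (samples x probes, methylation
fractions in [0, 1]) produced upstream by array preprocessing.  Probes are
first removed on annotation flags (sex chromosomes, SNP within 5 bp,
multi-mapping, cross-reactive), then features are selected unsupervised by
per-probe standard deviation across the full cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BetaMatrix",
    "FeatureSelectConfig",
    "FilterReport",
    "filter_probes",
    "select_features_by_sd",
    "read_annotation_tsv",
]

FLAG_COLUMNS = (
    "on_sex_chromosome",
    "snp_within_5bp",
    "multimap_hg19",
    "cross_reactive",
)


@dataclass
class BetaMatrix:
    """Samples x probes methylation fractions in [0, 1].

    ``values`` has shape (n_samples, n_probes); ids are unique and aligned
    to the rows / columns.  Missing values are rejected at construction —
    imputation is deliberately not offered.
    """

    sample_ids: np.ndarray
    probe_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.sample_ids.size, self.probe_ids.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{self.sample_ids.size} samples x {self.probe_ids.size} probes"
            )
        if np.unique(self.sample_ids).size != self.sample_ids.size:
            raise ValueError("sample_ids must be unique")
        if np.unique(self.probe_ids).size != self.probe_ids.size:
            raise ValueError("probe_ids must be unique")
        if self.values.size:
            if np.isnan(self.values).any():
                raise ValueError("beta matrix contains missing values")
            if self.values.min() < 0.0 or self.values.max() > 1.0:
                raise ValueError("beta values must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return int(self.sample_ids.size)

    @property
    def n_probes(self) -> int:
        return int(self.probe_ids.size)

    # ---- construction / round-tripping -------------------------------
    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BetaMatrix":
        """Build from a samples x probes DataFrame."""
        return cls(
            sample_ids=frame.index.to_numpy(),
            probe_ids=frame.columns.to_numpy(),
            values=frame.to_numpy(dtype=float),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.probe_ids)

    def subset_probes(self, keep: np.ndarray) -> "BetaMatrix":
        """Column subset by boolean mask or index array, order preserved."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return BetaMatrix(
            sample_ids=self.sample_ids,
            probe_ids=self.probe_ids[keep],
            values=self.values[:, keep],
        )

    @classmethod
    def read_tsv(cls, path) -> "BetaMatrix":
        """Read a probes-as-rows TSV (header row of sample ids)."""
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_frame(frame.T)

    def write_tsv(self, path) -> None:
        self.to_frame().T.to_csv(path, sep="\t", index_label="probe_id")

    @classmethod
    def read_h5(cls, path) -> "BetaMatrix":
        with h5py.File(path, "r") as h5:
            values = h5["beta"][()]  # probes x samples on disk
            probe_ids = h5["probe_ids"].asstr()[()]
            sample_ids = h5["sample_ids"].asstr()[()]
        return cls(sample_ids=sample_ids, probe_ids=probe_ids, values=values.T)

    def write_h5(self, path) -> None:
        with h5py.File(path, "w") as h5:
            h5.create_dataset("beta", data=self.values.T)
            h5.create_dataset(
                "probe_ids", data=np.asarray(self.probe_ids, dtype="S")
            )
            h5.create_dataset(
                "sample_ids", data=np.asarray(self.sample_ids, dtype="S")
            )


@dataclass(frozen=True)
class FeatureSelectConfig:
    """Standard-deviation cutoff for unsupervised feature selection.

    The default 0.3 is the cutoff used on full 450K reference cohorts;
    probes with sample SD strictly greater than the cutoff are kept.
    """

    sd_threshold: float = 0.3

    def __post_init__(self) -> None:
        if self.sd_threshold < 0:
            raise ValueError("sd_threshold must be >= 0")


@dataclass
class FilterReport:
    """Per-reason counts of probes removed by :func:`filter_probes`."""

    removed_by_reason: Dict[str, int] = field(default_factory=dict)
    n_removed: int = 0
    n_kept: int = 0

    def to_dict(self) -> dict:
        return {
            "removed_by_reason": dict(self.removed_by_reason),
            "n_removed": self.n_removed,
            "n_kept": self.n_kept,
        }


def read_annotation_tsv(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    missing = [c for c in ("probe_id",) + FLAG_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation is missing columns: {missing}")
    return ann


def filter_probes(beta: BetaMatrix, ann: pd.DataFrame):
    """Remove probes carrying any of the four annotation flags.

    A probe is removed if *any* flag is set (disjunctive reading of the
    exclusion criteria).  Sample order and relative probe order are
    preserved.  Returns the filtered matrix and a :class:`FilterReport`
    counting removals per reason (overlapping flags count once per reason).
    """
    if ann.index.name == "probe_id":
        ann = ann.reset_index()
    ann = ann.set_index("probe_id")
    missing = [p for p in beta.probe_ids if p not in ann.index]
    if missing:
        raise KeyError(
            f"{len(missing)} probes missing from annotation, e.g. {missing[:5]}"
        )
    flags = ann.loc[list(beta.probe_ids), list(FLAG_COLUMNS)].to_numpy(dtype=bool)
    remove = flags.any(axis=1)
    report = FilterReport(
        removed_by_reason={
            col: int(flags[:, i].sum()) for i, col in enumerate(FLAG_COLUMNS)
        },
        n_removed=int(remove.sum()),
        n_kept=int((~remove).sum()),
    )
    logger.info("filter_probes: removed %d probes (%s)", report.n_removed,
                report.removed_by_reason)
    return beta.subset_probes(~remove), report


def select_features_by_sd(
    beta: BetaMatrix, cfg: FeatureSelectConfig = FeatureSelectConfig()
) -> BetaMatrix:
    """Keep probes whose sample SD (ddof=1, all samples) exceeds the cutoff.

    The SD is computed across the entire cohort before any train/test
    split, reproducing the reference design; note this leaks unlabeled-data
    variance into feature selection (documented in the methods note).
    Strict inequality: a probe at exactly the threshold is dropped.
    """
    if beta.n_samples < 2:
        raise ValueError("sample SD needs >= 2 samples")
    sd = beta.values.std(axis=0, ddof=1)
    keep = sd > cfg.sd_threshold
    if not keep.any():
        logger.warning(
            "select_features_by_sd: no probe exceeds SD threshold %.3f",
            cfg.sd_threshold,
        )
    return beta.subset_probes(keep)
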