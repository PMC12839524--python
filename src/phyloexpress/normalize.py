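"""Median-of-ratios normalization and orthogroup-level aggregation.

Normalization is computed within each species (the species have different
reference transcriptomes, so a joint matrix is meaningless); cross-species
comparability is carried by the downstream models. The stated order of
operations is normalize first, then sum normalized transcript expression to
the orthogroup level per sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import OrthogroupMap, TranscriptCountMatrix

__all__ = [
    "SizeFactorError",
    "OrthogroupExpressionMatrix",
    "compute_size_factors",
    "normalize",
    "aggregate_to_orthogroups",
    "restrict_to_core",
]


class SizeFactorError(ValueError):
    """No usable reference transcripts for median-of-ratios normalization."""


@dataclass
class OrthogroupExpressionMatrix:
    """Summed normalized expression, orthogroups x samples (all species).

    ``copy_numbers`` holds the per-orthogroup per-species transcript counts and
    ``unassigned_fraction`` the per-species share of transcripts outside any
    orthogroup (those are excluded from the matrix but kept for transcript-level
    work).
    """

    values: pd.DataFrame  # orthogroups x samples, float
    copy_numbers: pd.DataFrame  # orthogroups x species, int
    sample_species: pd.Series  # sample_id -> species_id
    unassigned_fraction: pd.Series  # species_id -> fraction of transcripts

    @property
    def species_ids(self):
        return list(self.copy_numbers.columns)

    def restricted_report(self) -> dict:
        core = (self.copy_numbers.loc[self.values.index] >= 1).all(axis=1)
        return {"n_orthogroups": int(len(self.values)), "n_core": int(core.sum())}


def compute_size_factors(
    tcm: TranscriptCountMatrix, *, allow_pseudo_reference: bool = False
) -> pd.Series:
    """DESeq2-style median-of-ratios size factors, rescaled to geometric mean 1.

    For each sample j, s_j = median over reference transcripts of
    count(t, j) / geomean_samples(count(t, .)); the reference set is the
    transcripts with strictly positive counts in every sample (positive
    geometric mean). If that set is empty the default is an error with a
    remediation hint; ``allow_pseudo_reference`` instead falls back to
    transcripts positive in at least half of the samples, with the geometric
    mean taken over their positive entries only.
    """
    counts = tcm.counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(counts)
    all_positive = np.isfinite(logs).all(axis=1)
    if all_positive.any():
        geo = np.exp(logs[all_positive].mean(axis=1))
        ratios = counts[all_positive] / geo[:, None]
        sf = np.median(ratios, axis=0)
    elif allow_pseudo_reference:
        pos_frac = np.isfinite(logs).mean(axis=1)
        ref = pos_frac >= 0.5
        if not ref.any():
            raise SizeFactorError(
                f"species {tcm.species_id!r}: no transcript positive in half the "
                "samples; matrix too sparse to normalize"
            )
        # geometric mean over the positive entries of each reference transcript
        geo = np.exp(np.nanmean(np.where(np.isfinite(logs), logs, np.nan)[ref], axis=1))
        sf = np.median(counts[ref] / geo[:, None], axis=0)
        if (sf <= 0).any():
            raise SizeFactorError(
                f"species {tcm.species_id!r}: pseudo-reference still yields a "
                "zero size factor; matrix too sparse to normalize"
            )
    else:
        raise SizeFactorError(
            f"species {tcm.species_id!r}: no transcript has positive counts in "
            "all samples; pass allow_pseudo_reference=True to fall back to a "
            "pseudo-reference over partially observed transcripts"
        )
    sf = sf / np.exp(np.log(sf).mean())  # geometric mean 1
    return pd.Series(sf, index=tcm.counts.columns, name="size_factor")


def normalize(tcm: TranscriptCountMatrix, factors: pd.Series) -> pd.DataFrame:
    """Divide each sample's counts by its size factor."""
    missing = [s for s in tcm.counts.columns if s not in factors.index]
    if missing:
        raise KeyError(f"size factors missing for samples {missing[:5]}")
    f = factors.loc[tcm.counts.columns]
    if (f <= 0).any():
        raise ValueError("size factors must be positive")
    return tcm.counts / f


def aggregate_to_orthogroups(
    normalized: dict, og_map: OrthogroupMap
) -> OrthogroupExpressionMatrix:
    """Sum normalized transcript expression per orthogroup per sample.

    ``normalized`` maps species_id -> normalized transcript x sample DataFrame.
    Transcripts not assigned to any orthogroup are excluded from the matrix and
    reported in ``unassigned_fraction``; a sample occurring in two species
    matrices is an error.
    """
    ogs = og_map.orthogroup_ids
    og_index = pd.Index(ogs, name="orthogroup_id")
    blocks, sample_species, unassigned = [], {}, {}
    for sp, mat in normalized.items():
        for sid in mat.columns:
            if sid in sample_species:
                raise ValueError(f"sample {sid!r} appears in two species matrices")
            sample_species[sid] = sp
        tx2og = og_map.transcript_to_orthogroup(sp)
        assigned = mat.index.map(tx2og.get)
        n_unassigned = int(pd.isna(assigned).sum())
        unassigned[sp] = n_unassigned / len(mat.index) if len(mat.index) else 0.0
        sub = mat[~pd.isna(assigned)]
        groups = pd.Index(assigned[~pd.isna(assigned)], name="orthogroup_id")
        summed = sub.groupby(groups).sum().reindex(og_index, fill_value=0.0)
        blocks.append(summed)
    values = pd.concat(blocks, axis=1)
    return OrthogroupExpressionMatrix(
        values=values,
        copy_numbers=og_map.copy_numbers(),
        sample_species=pd.Series(sample_species, name="species_id"),
        unassigned_fraction=pd.Series(unassigned, name="unassigned_fraction"),
    )


def restrict_to_core(ogem: OrthogroupExpressionMatrix) -> OrthogroupExpressionMatrix:
    """Keep exactly the orthogroups with >= 1 copy in every species."""
    cn = ogem.copy_numbers.loc[ogem.values.index]
    core = cn.index[(cn >= 1).all(axis=1)]
    return OrthogroupExpressionMatrix(
        values=ogem.values.loc[core],
        copy_numbers=ogem.copy_numbers,
        sample_species=ogem.sample_species,
        unassigned_fraction=ogem.unassigned_fraction,
    )
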