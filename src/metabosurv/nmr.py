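"""Untargeted NMR spectral-bin screening.

Spectra are represented already segmented into 0.01-ppm bins on the standard
axis 0.505-9.495 ppm (900 bins).  The screen normalizes each spectrum, Pareto
scales the bin columns, computes a per-bin Welch t statistic between the
outcome groups (convention: positive t = higher mean in the case group),
flags bins with two-sided p below the screening alpha, and annotates flagged
bins with metabolite names from a chemical-shift lookup table.

The residual-water region, default [4.50, 5.00) ppm, is dropped from screen
output; the cut keeps the alpha-glucose reference doublet at 5.23 ppm on
axis.  The lookup table is a toy interval library for simulation and
labelling, not a curated chemical-shift database.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AXIS_LO",
    "AXIS_HI",
    "BIN_WIDTH",
    "WATER_REGION",
    "SpectralMatrix",
    "AnnotationLibrary",
    "bin_axis",
    "bin_index",
    "normalize_to_reference",
    "normalize_total_area",
    "pareto_scale",
    "welch_t",
    "screen_bins",
    "annotate_bins",
]

logger = logging.getLogger(__name__)

AXIS_LO = 0.505
AXIS_HI = 9.495
BIN_WIDTH = 0.01
WATER_REGION = (4.50, 5.00)  # [lo, hi): residual-water bins excluded from screens


def bin_axis(exclude_water: bool = False, water_region: tuple = WATER_REGION) -> np.ndarray:
    """The standard 0.01-ppm bin-center axis, optionally without water bins.

    900 centers 0.505, 0.515, ..., 9.495; excluding the default water
    interval [4.50, 5.00) removes 50 of them.
    """
    n = int(round((AXIS_HI - AXIS_LO) / BIN_WIDTH)) + 1
    centers = AXIS_LO + BIN_WIDTH * np.arange(n)
    if exclude_water:
        lo, hi = water_region
        centers = centers[(centers < lo) | (centers >= hi)]
    return np.round(centers, 3)


def bin_index(axis: np.ndarray, ppm: float) -> int:
    """Index of the bin whose half-open interval [c-0.005, c+0.005) holds
    ``ppm``; raises if the position falls off the axis."""
    axis = np.asarray(axis, dtype=float)
    j = int(np.searchsorted(axis + BIN_WIDTH / 2, ppm, side="right"))
    if j >= len(axis) or ppm < axis[j] - BIN_WIDTH / 2:
        raise ValueError(f"ppm position {ppm} is not covered by the bin axis")
    return j


@dataclass
class SpectralMatrix:
    """Patients x ppm-bin intensity matrix.

    Bin centers must be strictly increasing multiples of 0.01 ppm inside the
    standard axis (a subset of the full axis is allowed, e.g. after water
    removal); intensities finite with one row per patient.
    """

    patient_ids: list[str]
    bin_centers: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        # C-contiguous so reductions sum in one reproducible order no matter
        # where the matrix came from (generator or TSV reader)
        self.intensities = np.ascontiguousarray(self.intensities, dtype=float)
        self.patient_ids = [str(p) for p in self.patient_ids]
        if self.intensities.shape != (len(self.patient_ids), len(self.bin_centers)):
            raise ValueError("intensity matrix shape must be (patients, bins)")
        if len(self.bin_centers) == 0:
            raise ValueError("empty bin axis")
        d = np.diff(self.bin_centers)
        if np.any(d <= 0):
            raise ValueError("bin centers must be strictly increasing")
        steps = d / BIN_WIDTH
        if np.any(np.abs(steps - np.round(steps)) > 1e-7):
            raise ValueError("bin centers must lie on the 0.01-ppm grid")
        if self.bin_centers[0] < AXIS_LO - 1e-9 or self.bin_centers[-1] > AXIS_HI + 1e-9:
            raise ValueError(f"bin centers must lie within [{AXIS_LO}, {AXIS_HI}]")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise ValueError("duplicate patient ids")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{c:.3f}" for c in self.bin_centers]
        frame = pd.DataFrame(self.intensities, columns=cols)
        frame.insert(0, "patient_id", self.patient_ids)
        return frame


@dataclass
class AnnotationLibrary:
    """Metabolite name -> list of ppm intervals [lo, hi], all within the
    standard axis.  A toy lookup for simulation and labelling."""

    entries: dict[str, list[tuple[float, float]]]

    def __post_init__(self):
        # an empty library is legal (nothing annotates); a listed metabolite
        # must carry at least one interval
        clean: dict[str, list[tuple[float, float]]] = {}
        for name, intervals in self.entries.items():
            if not intervals:
                raise ValueError(f"metabolite {name!r} has no intervals")
            ivs = []
            for lo, hi in intervals:
                lo, hi = float(lo), float(hi)
                if lo > hi:
                    raise ValueError(f"interval ({lo}, {hi}) of {name!r} is inverted")
                if lo < AXIS_LO - BIN_WIDTH / 2 or hi > AXIS_HI + BIN_WIDTH / 2:
                    raise ValueError(
                        f"interval ({lo}, {hi}) of {name!r} lies outside the bin axis"
                    )
                ivs.append((lo, hi))
            clean[str(name)] = ivs
        self.entries = clean

    def metabolites_at(self, ppm: float) -> list[str]:
        """Sorted metabolite names whose intervals contain ``ppm``."""
        return sorted(
            name
            for name, ivs in self.entries.items()
            if any(lo <= ppm <= hi for lo, hi in ivs)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (name, lo, hi) for name, ivs in self.entries.items() for lo, hi in ivs
        ]
        return pd.DataFrame(rows, columns=["metabolite", "ppm_lo", "ppm_hi"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "AnnotationLibrary":
        frame = pd.read_csv(path)
        missing = {"metabolite", "ppm_lo", "ppm_hi"} - set(frame.columns)
        if missing:
            raise ValueError(f"annotation CSV missing columns: {sorted(missing)}")
        entries: dict[str, list[tuple[float, float]]] = {}
        for _, row in frame.iterrows():
            entries.setdefault(row["metabolite"], []).append(
                (float(row["ppm_lo"]), float(row["ppm_hi"]))
            )
        return cls(entries)


def default_annotation_library() -> AnnotationLibrary:
    """Toy chemical-shift assignments for the four metabolites the screen is
    expected to recover.  Placeholder intervals in physiologically plausible
    spectral neighbourhoods, not curated reference shifts."""
    return AnnotationLibrary(
        {
            "Phe": [(7.30, 7.45)],
            "Gln": [(2.42, 2.48)],
            "HDL-CH3": [(0.80, 0.90)],
            "Ketoglutarate": [(2.98, 3.02)],
        }
    )


def normalize_to_reference(matrix: SpectralMatrix, reference_bin: float) -> SpectralMatrix:
    """Divide every spectrum by its own intensity in the reference bin.

    The reference bin becomes exactly 1 in every row.  Non-positive reference
    intensity raises an error naming the patient.
    """
    j = bin_index(matrix.bin_centers, reference_bin)
    ref = matrix.intensities[:, j]
    bad = np.flatnonzero(ref <= 0)
    if bad.size:
        raise ValueError(
            f"non-positive reference intensity for patient {matrix.patient_ids[bad[0]]!r}"
        )
    return SpectralMatrix(
        matrix.patient_ids, matrix.bin_centers, matrix.intensities / ref[:, None]
    )


def normalize_total_area(matrix: SpectralMatrix) -> SpectralMatrix:
    """Divide every spectrum by its total intensity (alternative to
    reference-bin division)."""
    total = matrix.intensities.sum(axis=1)
    bad = np.flatnonzero(total <= 0)
    if bad.size:
        raise ValueError(
            f"non-positive total intensity for patient {matrix.patient_ids[bad[0]]!r}"
        )
    return SpectralMatrix(
        matrix.patient_ids, matrix.bin_centers, matrix.intensities / total[:, None]
    )


def pareto_scale(matrix: SpectralMatrix) -> SpectralMatrix:
    """Pareto scaling: per bin, subtract the mean and divide by the square
    root of the sample standard deviation (n-1 denominator).

    Intermediate between mean centering and unit-variance scaling; constant
    bins become all zeros with a logged warning.
    """
    if matrix.n_patients < 2:
        raise ValueError("Pareto scaling needs at least 2 patients")
    X = matrix.intensities
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        logger.warning(
            "%d constant bin(s) set to zero during Pareto scaling (e.g. %.3f ppm)",
            int(zero.sum()),
            matrix.bin_centers[np.flatnonzero(zero)[0]],
        )
    denom = np.where(zero, 1.0, np.sqrt(sd))
    scaled = np.where(zero, 0.0, (X - mean) / denom)
    return SpectralMatrix(matrix.patient_ids, matrix.bin_centers, scaled)


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t test.

    Returns ``(t, df, p)`` with Welch-Satterthwaite degrees of freedom and a
    two-sided p-value.  Each group needs >= 2 values and at least one group
    must have positive variance.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("groups contain non-finite values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("both group variances are zero")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def screen_bins(
    matrix: SpectralMatrix,
    hcc_labels,
    alpha: float = 0.01,
    water_region: tuple | None = WATER_REGION,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Per-bin Welch screen of cases against controls.

    One row per non-water bin, ordered by bin center, with t computed as case
    group minus control group (positive t = higher mean among patients who
    develop the outcome).  Bins with p <= ``alpha`` are flagged significant;
    by default the raw p is used with no multiplicity correction, matching
    the exploratory-screen convention; ``bh_correction=True`` flags on
    Benjamini-Hochberg adjusted p instead.

    Bins constant within both groups (e.g. a normalization reference bin)
    cannot be tested; they get NaN statistics and are never flagged.
    """
    labels = np.asarray(hcc_labels).astype(int)
    if len(labels) != matrix.n_patients:
        raise ValueError("labels must align with patient_ids")
    if labels.min() == labels.max():
        raise ValueError("both outcome groups must be non-empty")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    keep = np.ones(len(matrix.bin_centers), dtype=bool)
    if water_region is not None:
        lo, hi = water_region
        keep = (matrix.bin_centers < lo) | (matrix.bin_centers >= hi)
    centers = matrix.bin_centers[keep]
    cases = matrix.intensities[labels == 1][:, keep]
    controls = matrix.intensities[labels == 0][:, keep]
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(cases, controls, axis=0, equal_var=False)
        tstat = np.asarray(res.statistic, dtype=float)
        df = np.asarray(res.df, dtype=float)
        pval = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(tstat)
    if degenerate.any():
        logger.warning(
            "%d degenerate bin(s) (zero variance in both groups) excluded from the screen",
            int(degenerate.sum()),
        )
        pval = np.where(degenerate, np.nan, pval)
        df = np.where(degenerate, np.nan, df)
        tstat = np.where(degenerate, np.nan, tstat)
    flag_p = pval
    if bh_correction:
        ok = np.isfinite(pval)
        adj = np.full_like(pval, np.nan)
        adj[ok] = stats.false_discovery_control(pval[ok], method="bh")
        flag_p = adj
    with np.errstate(invalid="ignore"):
        significant = np.where(np.isfinite(flag_p), flag_p <= alpha, False).astype(bool)
    direction = np.where(np.isfinite(tstat), np.where(tstat >= 0, "positive", "negative"), "")
    return pd.DataFrame(
        {
            "bin_center": centers,
            "t_stat": tstat,
            "df": df,
            "p_value": pval,
            "direction": direction,
            "significant": significant,
            "annotation": pd.Series([""] * len(centers), dtype=object),
        }
    )


def annotate_bins(rows: pd.DataFrame, library: AnnotationLibrary) -> pd.DataFrame:
    """Attach metabolite names to significant screen rows whose bin center
    falls inside a library interval; overlapping assignments are joined with
    ';' in sorted order."""
    out = rows.copy()
    ann = []
    for _, row in out.iterrows():
        if row["significant"]:
            names = library.metabolites_at(float(row["bin_center"]))
            ann.append(";".join(names))
        else:
            ann.append("")
    out["annotation"] = ann
    return out
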