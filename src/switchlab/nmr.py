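"""Methyl-TROSY peak-list analysis: matching, assignment, CSP, PRE.

Works at the peak-list level (label, 13C ppm, 1H ppm, height), the form
exported by Sparky.  Chemical-shift perturbation between a reference and a
bound/mutant spectrum is combined across dimensions as

    dnu = sqrt( dH^2 + (alpha_C * dC)^2 )

with alpha_C = 0.25, the conventional down-weighting of the wider 13C
dispersion, and classified against slight/moderate/significant thresholds
(0.005/0.010/0.020 ppm, strict inequality).  Paramagnetic relaxation
enhancement (PRE) from a nitroxide-labelled ligand is scored per methyl as
the intensity ratio I_PRE/I_0 (1 = untouched, 0 = erased), then multiplied
by the residue's fractional solvent accessibility so that broadening of
buried methyls — which the free spin label cannot reach nonspecifically —
ranks highest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Peak",
    "PeakList",
    "CSPThresholds",
    "CSPRecord",
    "PRERecord",
    "read_sparky",
    "write_sparky",
    "match_peaks",
    "assign_by_disappearance",
    "combined_csp",
    "csp_profile",
    "pre_profile",
    "category_counts",
]

CATEGORY_ORDER = ("none", "slight", "moderate", "significant")


@dataclass(frozen=True)
class Peak:
    """One 2-D cross peak: label, 13C shift (w1), 1H shift (w2), height."""

    label: str
    w_C: float
    w_H: float
    height: float = 1.0

    def __post_init__(self):
        if not (np.isfinite(self.w_C) and np.isfinite(self.w_H)):
            raise ValueError(f"peak {self.label!r}: shifts must be finite")
        if self.height < 0:
            raise ValueError(f"peak {self.label!r}: height must be >= 0")


@dataclass(frozen=True)
class PeakList:
    peaks: tuple[Peak, ...]

    def __init__(self, peaks):
        object.__setattr__(self, "peaks", tuple(peaks))

    def __len__(self):
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def labels(self) -> list[str]:
        return [p.label for p in self.peaks]

    def by_label(self) -> dict[str, Peak]:
        return {p.label: p for p in self.peaks}


@dataclass(frozen=True)
class CSPThresholds:
    """CSP category boundaries (ppm) and the 13C weight of the combined shift."""

    slight: float = 0.005
    moderate: float = 0.010
    significant: float = 0.020
    alpha_C: float = 0.25

    def __post_init__(self):
        if not 0 < self.slight < self.moderate < self.significant:
            raise ValueError("require 0 < slight < moderate < significant")

    def categorize(self, dnu: float) -> str:
        # strict inequalities: a shift sitting exactly on a boundary stays below it
        if dnu > self.significant:
            return "significant"
        if dnu > self.moderate:
            return "moderate"
        if dnu > self.slight:
            return "slight"
        return "none"


@dataclass(frozen=True)
class CSPRecord:
    label: str
    delta_H: float
    delta_C: float
    delta_nu: float
    category: str


@dataclass(frozen=True)
class PRERecord:
    label: str
    I_PRE: float
    I_0: float
    ratio: float
    sasa_frac: float
    normalized_pre: float


# ---------------------------------------------------------------- Sparky I/O


def read_sparky(path) -> PeakList:
    """Read a Sparky-style 4-column list: label, w1 (13C), w2 (1H), height.

    Lines starting with '#' or a header line beginning with 'Assignment'
    are skipped.
    """
    peaks = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("assignment"):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ValueError(f"malformed peak line: {line!r}")
        height = float(parts[3]) if len(parts) > 3 else 1.0
        peaks.append(Peak(parts[0], float(parts[1]), float(parts[2]), height))
    return PeakList(peaks)


def write_sparky(peaklist: PeakList, path) -> None:
    lines = ["Assignment  w1_ppm  w2_ppm  height"]
    for p in peaklist:
        lines.append(f"{p.label}  {p.w_C:.4f}  {p.w_H:.4f}  {p.height:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------- matching


def match_peaks(
    ref: PeakList,
    test: PeakList,
    tol_H: float = 0.03,
    tol_C: float = 0.15,
):
    """Mutual-nearest-neighbour peak matching in tolerance-scaled shift space.

    Distances are computed on (dH/tol_H, dC/tol_C); a pair matches only if
    each is the other's nearest peak and their scaled distance is <= 1.
    Returns (matches, unmatched_ref, unmatched_test) where matches is a
    list of (ref_peak, test_peak) pairs.
    """
    if tol_H <= 0 or tol_C <= 0:
        raise ValueError("tolerances must be positive")
    if len(ref) == 0 or len(test) == 0:
        return [], list(ref), list(test)
    A = np.array([[p.w_H / tol_H, p.w_C / tol_C] for p in ref])
    B = np.array([[p.w_H / tol_H, p.w_C / tol_C] for p in test])
    d = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=2)
    nn_ref = d.argmin(axis=1)
    nn_test = d.argmin(axis=0)
    matches = []
    used_test = set()
    for i, j in enumerate(nn_ref):
        if nn_test[j] == i and d[i, j] <= 1.0:
            matches.append((ref.peaks[i], test.peaks[int(j)]))
            used_test.add(int(j))
    matched_ref = {id(a) for a, _ in matches}
    unmatched_ref = [p for p in ref if id(p) not in matched_ref]
    unmatched_test = [p for j, p in enumerate(test.peaks) if j not in used_test]
    return matches, unmatched_ref, unmatched_test


def assign_by_disappearance(
    wt: PeakList,
    mutant: PeakList,
    tol_H: float = 0.03,
    tol_C: float = 0.15,
):
    """Assign methyl peaks by comparing wild-type and point-mutant spectra.

    An Ile->X mutant loses exactly its own isoleucine peak, so a wild-type
    peak with no mutant partner identifies that residue; an X->Ile mutant
    gains one (reported under 'appeared').  Returns a dict with keys
    'vanished', 'appeared', 'ambiguous' (True when more than one peak
    vanished or a vanish/appear pair suggests a large shift rather than a
    clean disappearance).
    """
    _, unmatched_wt, unmatched_mut = match_peaks(wt, mutant, tol_H, tol_C)
    vanished = [p.label for p in unmatched_wt]
    appeared = [p.label for p in unmatched_mut]
    ambiguous = len(vanished) > 1 or (len(vanished) >= 1 and len(appeared) >= 1)
    return {"vanished": vanished, "appeared": appeared, "ambiguous": ambiguous}


# ---------------------------------------------------------------- CSP


def combined_csp(ref: Peak, bound: Peak, thresholds: CSPThresholds = CSPThresholds()) -> CSPRecord:
    """Combined chemical-shift perturbation between two states of one site."""
    dH = bound.w_H - ref.w_H
    dC = bound.w_C - ref.w_C
    dnu = float(np.hypot(dH, thresholds.alpha_C * dC))
    return CSPRecord(
        label=ref.label,
        delta_H=dH,
        delta_C=dC,
        delta_nu=dnu,
        category=thresholds.categorize(dnu),
    )


def csp_profile(
    ref: PeakList,
    bound: PeakList,
    thresholds: CSPThresholds = CSPThresholds(),
    tol_H: float = 0.03,
    tol_C: float = 0.15,
    by_label: bool = True,
) -> list[CSPRecord]:
    """CSPs for every site present in both spectra.

    by_label pairs peaks sharing a label (assigned spectra); otherwise
    mutual-nearest matching is used, which suits unassigned fingerprint
    spectra (e.g. threonine regions) where only per-category counts are
    meaningful.
    """
    records = []
    if by_label:
        rmap, bmap = ref.by_label(), bound.by_label()
        for label in rmap:
            if label in bmap:
                records.append(combined_csp(rmap[label], bmap[label], thresholds))
    else:
        matches, _, _ = match_peaks(ref, bound, tol_H, tol_C)
        for a, b in matches:
            records.append(combined_csp(a, b, thresholds))
    return records


def category_counts(records: list[CSPRecord]) -> dict[str, int]:
    counts = {c: 0 for c in CATEGORY_ORDER}
    for r in records:
        counts[r.category] += 1
    return counts


# ---------------------------------------------------------------- PRE


def pre_profile(
    ref: PeakList,
    pre: PeakList,
    sasa: dict[str, float],
    tol_H: float = 0.03,
    tol_C: float = 0.15,
    invert: bool = False,
) -> list[PRERecord]:
    """Per-site PRE broadening, normalized by solvent accessibility.

    ratio = I_PRE/I_0 per label (0 for peaks erased by the spin label);
    sasa_frac = sasa/max(sasa); normalized_pre = ratio * sasa_frac.  Output
    is sorted ascending by normalized_pre, most broadened first.  Both
    spectra must be acquired/scaled comparably — ratios are only meaningful
    on a shared intensity scale.  ``invert`` reports I_0/I_PRE instead
    (the reciprocal convention; infinite for erased peaks, so off by
    default).
    """
    rmap = ref.by_label()
    pmap = pre.by_label()
    missing = [lab for lab in rmap if lab not in sasa]
    if missing:
        raise ValueError(f"missing SASA entries for labels: {sorted(missing)}")
    sasa_max = max(sasa[lab] for lab in rmap)
    if sasa_max <= 0:
        raise ValueError("all SASA values are zero")
    records = []
    for label, rp in rmap.items():
        if rp.height <= 0:
            raise ValueError(f"reference peak {label!r} has non-positive intensity")
        i_pre = pmap[label].height if label in pmap else 0.0
        ratio = (rp.height / i_pre if i_pre > 0 else float("inf")) if invert else i_pre / rp.height
        frac = sasa[label] / sasa_max
        records.append(
            PRERecord(
                label=label,
                I_PRE=i_pre,
                I_0=rp.height,
                ratio=ratio,
                sasa_frac=frac,
                normalized_pre=ratio * frac,
            )
        )
    records.sort(key=lambda r: (r.normalized_pre, r.label))
    return records


def pre_table(records: list[PRERecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "label": r.label,
                "ratio": r.ratio,
                "sasa_frac": r.sasa_frac,
                "normalized_pre": r.normalized_pre,
            }
            for r in records
        ]
    )


def csp_table(records: list[CSPRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "label": r.label,
                "delta_H": r.delta_H,
                "delta_C": r.delta_C,
                "delta_nu": r.delta_nu,
                "category": r.category,
            }
            for r in records
        ]
    )
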