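"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates one experimental data type consumed downstream —
peptide tiling arrays with an injected per-amino-acid weight model,
titrations drawn from the log-dose binding equation, peak-list pairs with
designated shifted/vanished peaks, ideal-helix CA traces, and per-band
cross-link abundance tables with designated inter-molecular links — so
recovery of the injected truth can be tested end to end without any
external dataset.

All generators are deterministic given their seed.  Array noise is seeded
per (spot, replicate) from a stable hash, so subsetting spots or
replicates never reshuffles the noise of the remainder.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arrays import AA_ALPHABET, ArrayDesign, PeptideArrayTable, tile_sequence
from .binding import BindingCurveData, BindingParams, binding_model
from .nmr import Peak, PeakList
from .structure import CrossLinkRecord, StructureModel

__all__ = [
    "AAWeightModel",
    "HelixSpec",
    "gen_array",
    "gen_titration",
    "gen_peaklists",
    "gen_helix",
    "gen_xlink_table",
    "client_sequences",
    "write_fasta",
    "write_titration_csv",
    "read_titration_csv",
]


def _stable_rng(seed: int, *tokens) -> np.random.Generator:
    """RNG keyed on (seed, tokens) via a stable hash — independent of
    Python's salted hash and of entity ordering."""
    h = hashlib.blake2b("\x1f".join(str(t) for t in tokens).encode(), digest_size=8)
    words = np.frombuffer(h.digest(), dtype=np.uint32)
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *map(int, words)]))


# ---------------------------------------------------------------- arrays


@dataclass(frozen=True)
class AAWeightModel:
    """Per-amino-acid log-intensity contributions plus log-normal noise.

    A spot's expected log intensity is the sum of its residues' weights;
    noise_sd is the sd of the additive Gaussian term on the log scale
    (multiplicative log-normal on the intensity scale, which keeps
    intensities positive as fluorescence data are).
    """

    weights: dict[str, float]
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        missing = set(AA_ALPHABET) - set(self.weights)
        if missing:
            raise ValueError(f"weights missing for amino acids: {sorted(missing)}")
        if not all(math.isfinite(w) for w in self.weights.values()):
            raise ValueError("weights must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @classmethod
    def uniform(cls, value: float = 0.0, noise_sd: float = 0.2, seed: int = 0) -> "AAWeightModel":
        return cls({aa: value for aa in AA_ALPHABET}, noise_sd, seed)

    @classmethod
    def with_preferences(
        cls, prefs: dict[str, float], baseline: float = 0.0, noise_sd: float = 0.2, seed: int = 0
    ) -> "AAWeightModel":
        w = {aa: baseline for aa in AA_ALPHABET}
        w.update(prefs)
        return cls(w, noise_sd, seed)


def gen_array(
    seqs: dict[str, str],
    model: AAWeightModel,
    replicates: int = 3,
    design: ArrayDesign = ArrayDesign(),
) -> PeptideArrayTable:
    """Simulate a tiling array: spots tile each sequence, intensities
    follow the injected weight model.

    raw intensity of spot s in replicate r = exp(sum of weights over the
    spot's residues + eps), eps ~ Normal(0, noise_sd^2) seeded per
    (spot, replicate).
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    rows = []
    for protein_id, seq in seqs.items():
        for start, tile in tile_sequence(seq, design):
            spot_id = f"{protein_id}:{start}"
            log_mu = sum(model.weights[aa] for aa in tile)
            for rep in range(1, replicates + 1):
                rng = _stable_rng(model.seed, "array", spot_id, rep)
                eps = rng.normal(0.0, model.noise_sd) if model.noise_sd > 0 else 0.0
                rows.append(
                    {
                        "spot_id": spot_id,
                        "protein_id": protein_id,
                        "start_1based": start,
                        "sequence": tile,
                        "replicate": rep,
                        "intensity": math.exp(log_mu + eps),
                    }
                )
    return PeptideArrayTable(pd.DataFrame(rows))


#: Lengths of the five client proteins a tiling array typically spans
#: (a misfolded carboxypeptidase, myelin protein zero, insulin, lysozyme
#: and a large nuclear protein fragment) — used for realistic array sizes.
CLIENT_LENGTHS = {
    "cpy_like": 530,
    "mpz_like": 248,
    "insulin_like": 110,
    "lysozyme_like": 130,
    "ptip_like": 335,
}


def client_sequences(seed: int = 0, lengths: dict[str, int] | None = None) -> dict[str, str]:
    """Random client-protein sequences at realistic tiled-protein lengths."""
    lengths = lengths or CLIENT_LENGTHS
    return {
        name: "".join(_stable_rng(seed, "client", name).choice(list(AA_ALPHABET), size=L))
        for name, L in lengths.items()
    }


# ---------------------------------------------------------------- titrations


def gen_titration(
    params: BindingParams,
    x_grid,
    noise_sd: float = 0.005,
    seed: int = 0,
) -> BindingCurveData:
    """Draw one titration from the binding model with Gaussian response noise."""
    x = np.asarray(x_grid, dtype=float)
    if x.size < 6:
        raise ValueError("x_grid must have at least 6 points")
    if np.any(np.diff(x) < 0):
        raise ValueError("x_grid must be sorted ascending")
    y = binding_model(x, params)
    if noise_sd > 0:
        y = y + _stable_rng(seed, "titration").normal(0.0, noise_sd, size=x.size)
    return BindingCurveData(x, y)


# ---------------------------------------------------------------- peak lists


def gen_peaklists(
    base: PeakList,
    shifted: dict[str, tuple[float, float]] | None = None,
    vanished: set[str] | None = None,
    seed: int = 0,
    height_jitter: float = 0.0,
) -> tuple[PeakList, PeakList]:
    """Derive a perturbed spectrum from a base peak list.

    ``shifted`` maps label -> (delta_H, delta_C) in ppm; ``vanished``
    labels are removed (mimicking mutation or paramagnetic erasure).
    Heights of surviving peaks are preserved up to optional multiplicative
    jitter.  Returns (reference, perturbed).
    """
    shifted = dict(shifted or {})
    vanished = set(vanished or ())
    known = set(base.labels())
    unknown = (set(shifted) | vanished) - known
    if unknown:
        raise ValueError(f"labels not in base list: {sorted(unknown)}")
    out = []
    for p in base:
        if p.label in vanished:
            continue
        dH, dC = shifted.get(p.label, (0.0, 0.0))
        h = p.height
        if height_jitter > 0:
            h *= math.exp(_stable_rng(seed, "peak", p.label).normal(0.0, height_jitter))
        out.append(Peak(p.label, p.w_C + dC, p.w_H + dH, h))
    return base, PeakList(out)


# ---------------------------------------------------------------- helices


@dataclass(frozen=True)
class HelixSpec:
    """Ideal α-helix CA trace: radius 2.3 Å, rise 1.5 Å, twist 100°/res."""

    n_res: int
    radius: float = 2.3
    rise: float = 1.5
    twist: float = 100.0

    def __post_init__(self):
        if self.n_res < 2:
            raise ValueError("helix needs at least 2 residues")
        if min(self.radius, self.rise, self.twist) < 0 or self.rise == 0:
            raise ValueError("helix parameters must be positive")


def gen_helix(spec: HelixSpec, chain: str = "A", offset=(0.0, 0.0, 0.0)) -> StructureModel:
    """CA-only ideal helix: CA_i = (r cos(iθ), r sin(iθ), i·rise), i = 0..n-1,
    residues numbered 1..n on a single chain."""
    i = np.arange(spec.n_res, dtype=float)
    theta = np.deg2rad(spec.twist) * i
    coords = np.column_stack(
        [spec.radius * np.cos(theta), spec.radius * np.sin(theta), spec.rise * i]
    ) + np.asarray(offset, dtype=float)
    n = spec.n_res
    return StructureModel(
        chain=[chain] * n,
        resnum=np.arange(1, n + 1),
        resname=["ALA"] * n,
        atom_name=["CA"] * n,
        element=["C"] * n,
        coords=coords,
    )


def helix_ca_distance(spec: HelixSpec, sep: int) -> float:
    """Closed-form CA distance between residues i and i+sep of an ideal helix."""
    dtheta = math.radians(spec.twist * sep)
    return math.sqrt(
        2.0 * spec.radius**2 * (1.0 - math.cos(dtheta)) + (spec.rise * sep) ** 2
    )


# ---------------------------------------------------------------- cross-links


def gen_xlink_table(
    pairs: list[tuple[int, int]],
    inter_set: set[tuple[int, int]],
    band_count: int = 5,
    abundances: dict[tuple[int, int], float] | None = None,
    seed: int = 0,
    rel_noise: float = 0.15,
    condition: str = "synthetic",
) -> list[CrossLinkRecord]:
    """Simulate a per-band cross-link quantification table.

    Pairs in ``inter_set`` get zero abundance in the monomer band (band 1)
    and positive abundance in every oligomer band; all other pairs are
    present in the monomer band too (intra-molecular links form regardless
    of oligomerization).  ``abundances`` fixes each pair's nominal mean %
    (default 2.0); per-band values jitter around it by ``rel_noise``.
    """
    norm_inter = {tuple(sorted(p)) for p in inter_set}
    norm_pairs = [tuple(sorted(p)) for p in pairs]
    if not norm_inter <= set(norm_pairs):
        raise ValueError("inter_set must be a subset of pairs")
    if band_count < 2:
        raise ValueError("need a monomer band plus at least one oligomer band")
    abundances = abundances or {}
    out = []
    for a, b in norm_pairs:
        nominal = abundances.get((a, b), 2.0)
        bands = {}
        for band in range(1, band_count + 1):
            if band == 1 and (a, b) in norm_inter:
                bands[band] = (0.0, 0.0)
                continue
            rng = _stable_rng(seed, "xlink", a, b, band)
            mean = nominal * float(np.clip(1.0 + rng.normal(0.0, rel_noise), 0.05, None))
            sd = mean * rel_noise
            bands[band] = (min(mean, 100.0), sd)
        out.append(CrossLinkRecord(a, b, bands, condition))
    return out


# ---------------------------------------------------------------- writers


def write_fasta(seqs: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_titration_csv(data: BindingCurveData, path) -> None:
    pd.DataFrame({"conc_uM": 10.0**data.x, "response": data.response}).to_csv(path, index=False)


def read_titration_csv(path) -> BindingCurveData:
    df = pd.read_csv(path)
    return BindingCurveData.from_concentrations(df["conc_uM"], df["response"])
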