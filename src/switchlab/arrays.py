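"""Peptide tiling-array enrichment analysis.

Tiling arrays probe a sensor or chaperone against overlapping peptides
(18-mers stepping by 3 residues) spanning whole client-protein sequences.
After per-replicate normalization to the brightest spot, the top decile of
binders is selected and per-amino-acid enrichment is scored as

    E(a) = log2( f_top(a) / f_all(a) )

the log-ratio of residue frequency among top-binding peptides to frequency
across the whole array.  Replicate-wise E values support an unpaired
two-sided t-test against 0 (is amino acid *a* enriched/depleted?), and two
probes (e.g. a UPR sensor domain vs the Hsp70 chaperone BiP) are compared
amino acid by amino acid with the same test on E_A - E_B.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

__all__ = [
    "AA_ALPHABET",
    "ArrayDesign",
    "PeptideArrayTable",
    "EnrichmentResult",
    "tile_sequence",
    "normalize_array",
    "select_top",
    "aa_enrichment",
    "compare_probes",
]


@dataclass(frozen=True)
class ArrayDesign:
    """Array layout and scoring parameters.

    tile_length/step give 18-mers shifted by 3 residues; top_fraction the
    selected quantile of binders; alpha the significance level used when
    flagging amino acids.
    """

    tile_length: int = 18
    step: int = 3
    top_fraction: float = 0.10
    alpha: float = 0.05

    def __post_init__(self):
        if not 0 < self.step <= self.tile_length:
            raise ValueError("require 0 < step <= tile_length")
        if not 0 < self.top_fraction < 1:
            raise ValueError("top_fraction must be in (0, 1)")


@dataclass(frozen=True)
class PeptideArrayTable:
    """Spot table: one row per (spot, replicate) with a raw intensity.

    Columns: spot_id, protein_id, start_1based, sequence, replicate, intensity.
    """

    spots: pd.DataFrame

    COLUMNS = ("spot_id", "protein_id", "start_1based", "sequence", "replicate", "intensity")

    def __post_init__(self):
        df = self.spots
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"spot table missing columns: {sorted(missing)}")
        lens = df["sequence"].str.len().unique()
        if len(lens) > 1:
            raise ValueError("all tile sequences must share one length")
        inten = df["intensity"].to_numpy(dtype=float)
        if not np.all(np.isfinite(inten)) or np.any(inten < 0):
            raise ValueError("intensities must be finite and non-negative")

    @property
    def replicates(self) -> list:
        return sorted(self.spots["replicate"].unique())

    def to_csv(self, path) -> None:
        self.spots.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PeptideArrayTable":
        return cls(pd.read_csv(path))


@dataclass
class EnrichmentResult:
    """Per-amino-acid enrichment of top binders vs the whole array.

    ``table`` has one row per amino acid: log2_enrichment (mean over
    replicates when per-replicate), sd, p_value (NaN when not testable),
    flag.  ``per_replicate_E`` maps amino acid -> array of replicate E
    values (empty when pooled).  ``top_ids`` is the selected spot set
    (pooled selection) or the union over replicates.
    """

    table: pd.DataFrame
    per_replicate_E: dict[str, np.ndarray]
    top_ids: list
    n_replicates: int

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def tile_sequence(seq: str, design: ArrayDesign = ArrayDesign()) -> list[tuple[int, str]]:
    """Tile a protein sequence into (start_1based, tile) windows.

    Count = floor((L - tile_length)/step) + 1; raises on sequences shorter
    than one tile.
    """
    L = len(seq)
    if L < design.tile_length:
        raise ValueError(
            f"sequence of length {L} is shorter than the tile length {design.tile_length}"
        )
    starts = range(0, L - design.tile_length + 1, design.step)
    return [(s + 1, seq[s : s + design.tile_length]) for s in starts]


def normalize_array(table: PeptideArrayTable) -> PeptideArrayTable:
    """Scale each replicate so its brightest spot has intensity 1.

    Idempotent; raises if any replicate is all-zero.
    """
    df = table.spots.copy()
    for rep, sub in df.groupby("replicate"):
        m = sub["intensity"].max()
        if m <= 0:
            raise ValueError(f"replicate {rep!r} has no positive intensity")
        df.loc[sub.index, "intensity"] = sub["intensity"] / m
    return PeptideArrayTable(df)


def _mean_ranked_top(df: pd.DataFrame, top_fraction: float) -> list:
    per_spot = (
        df.groupby("spot_id", sort=False)
        .agg(intensity=("intensity", "mean"))
        .reset_index()
    )
    n_top = math.ceil(top_fraction * len(per_spot))
    per_spot = per_spot.sort_values(
        ["intensity", "spot_id"], ascending=[False, True], kind="mergesort"
    )
    return per_spot["spot_id"].head(n_top).tolist()


def select_top(table: PeptideArrayTable, design: ArrayDesign = ArrayDesign()) -> list:
    """Select the top-fraction spots by mean normalized intensity.

    Spots are ranked by their mean intensity across replicates; the top
    ceil(top_fraction * N) are returned.  Ties at the cut break by
    (intensity descending, spot_id ascending).
    """
    return _mean_ranked_top(table.spots, design.top_fraction)


def _per_replicate_tops(table: PeptideArrayTable, design: ArrayDesign) -> dict:
    return {
        rep: _mean_ranked_top(sub, design.top_fraction)
        for rep, sub in table.spots.groupby("replicate")
    }


def _composition(seqs) -> Counter:
    c: Counter = Counter()
    for s in seqs:
        c.update(s)
    return c


def _enrichment_vector(top_seqs, all_seqs, pseudo: float = 0.5):
    """log2 frequency ratio of top-set residues vs whole-array residues.

    Amino acids absent from the top set get a pseudo-count of ``pseudo``
    residues before the ratio (flagged depletion floor), keeping E finite.
    Returns dict aa -> (E, flag).
    """
    top = _composition(top_seqs)
    full = _composition(all_seqs)
    n_top = sum(top.values())
    n_full = sum(full.values())
    out = {}
    for aa in sorted(full):
        f_all = full[aa] / n_full
        if top.get(aa, 0) > 0:
            f_top = top[aa] / n_top
            out[aa] = (math.log2(f_top / f_all), "")
        else:
            f_top = pseudo / n_top
            out[aa] = (math.log2(f_top / f_all), "depletion_floor")
    return out


def aa_enrichment(
    table: PeptideArrayTable,
    design: ArrayDesign = ArrayDesign(),
    per_replicate: bool = True,
    top_ids: list | None = None,
    adjust: str | None = None,
) -> EnrichmentResult:
    """Score per-amino-acid enrichment among top-binding peptides.

    per_replicate=True selects a top set within each replicate and tests
    the replicate E values against 0 with an unpaired two-sided t-test
    (needs >= 2 replicates).  per_replicate=False pools replicates with a
    single mean-ranked top set; no p-values are produced.  ``top_ids``
    overrides selection (pooled mode only).  ``adjust='bh'`` applies a
    Benjamini-Hochberg correction (off by default; reported p-values are
    otherwise unadjusted).
    """
    norm = normalize_array(table)
    df = norm.spots
    seq_of = df.drop_duplicates("spot_id").set_index("spot_id")["sequence"]
    all_seqs = seq_of.tolist()

    per_rep_E: dict[str, list[float]] = {}
    flags: dict[str, set] = {}

    if per_replicate:
        tops = _per_replicate_tops(norm, design)
        n_rep = len(tops)
        union_top: list = sorted({sid for ids in tops.values() for sid in ids})
        for rep, ids in tops.items():
            vec = _enrichment_vector([seq_of[i] for i in ids], all_seqs)
            for aa, (e, fl) in vec.items():
                per_rep_E.setdefault(aa, []).append(e)
                if fl:
                    flags.setdefault(aa, set()).add(fl)
        rows = []
        for aa, evals in per_rep_E.items():
            ev = np.asarray(evals)
            if n_rep >= 2:
                sd = float(ev.std(ddof=1))
                if sd == 0.0:
                    # identical replicate values: degenerate t; certainty
                    p = 0.0 if ev.mean() != 0 else 1.0
                else:
                    p = float(stats.ttest_1samp(ev, 0.0).pvalue)
            else:
                sd, p = float("nan"), float("nan")
                flags.setdefault(aa, set()).add("p_undefined")
            rows.append(
                {
                    "aa": aa,
                    "log2_enrichment": float(ev.mean()),
                    "sd": sd,
                    "p_value": p,
                    "flag": ";".join(sorted(flags.get(aa, ()))),
                }
            )
        top_out = union_top
    else:
        ids = top_ids if top_ids is not None else select_top(norm, design)
        n_rep = len(norm.replicates)
        vec = _enrichment_vector([seq_of[i] for i in ids], all_seqs)
        rows = [
            {"aa": aa, "log2_enrichment": e, "sd": float("nan"),
             "p_value": float("nan"), "flag": fl}
            for aa, (e, fl) in vec.items()
        ]
        top_out = list(ids)

    tab = pd.DataFrame(rows).sort_values("aa").reset_index(drop=True)
    if adjust == "bh" and tab["p_value"].notna().any():
        from statsmodels.stats.multitest import multipletests

        ok = tab["p_value"].notna()
        tab.loc[ok, "p_value"] = multipletests(tab.loc[ok, "p_value"], method="fdr_bh")[1]
    return EnrichmentResult(
        table=tab,
        per_replicate_E={aa: np.asarray(v) for aa, v in per_rep_E.items()},
        top_ids=top_out,
        n_replicates=n_rep,
    )


def compare_probes(result_a: EnrichmentResult, result_b: EnrichmentResult) -> pd.DataFrame:
    """Compare binding preferences of two probes amino acid by amino acid.

    Requires per-replicate E values on both sides; returns delta_E
    (= E_A - E_B) and an unpaired two-sided t-test p-value per amino acid.
    Amino acids present on only one side are excluded with a warning;
    with < 2 replicates on either side p is NaN and flagged.
    """
    a, b = result_a.per_replicate_E, result_b.per_replicate_E
    if not a or not b:
        raise ValueError("both results need per-replicate E values (per_replicate=True)")
    only = sorted(set(a) ^ set(b))
    if only:
        warnings.warn(f"amino acids absent from one probe excluded: {only}")
    rows = []
    for aa in sorted(set(a) & set(b)):
        ea, eb = a[aa], b[aa]
        flag = ""
        if len(ea) < 2 or len(eb) < 2:
            p = float("nan")
            flag = "p_undefined"
        elif ea.std(ddof=1) == 0 and eb.std(ddof=1) == 0:
            p = 1.0 if ea.mean() == eb.mean() else 0.0
        else:
            p = float(stats.ttest_ind(ea, eb).pvalue)
        rows.append(
            {
                "aa": aa,
                "delta_E": float(ea.mean() - eb.mean()),
                "p_value": p,
                "flag": flag,
            }
        )
    return pd.DataFrame(rows)
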