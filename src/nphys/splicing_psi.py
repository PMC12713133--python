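"""Exon percent-spliced-in (PSI) quantification and differential inclusion.

Psi for a cassette exon is the junction-ratio estimate
``Psi = I_eff / (I_eff + S)`` where ``I_eff`` is the mean of the
available inclusion-junction counts (upstream and downstream of the
exon) and ``S`` the skipping-junction count. Differential inclusion
between two groups is tested with a two-sided Fisher exact test on the
pooled 2x2 inclusion/skipping table, with Benjamini-Hochberg adjustment
across exons. RT-PCR band intensities are converted to Psi with optional
molar correction for amplicon length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_fdr

MIN_COVERAGE = 10       # effective reads below which Psi is undefined
CODON_NT = 3


@dataclass
class PsiRecord:
    exon_id: str
    sample_id: str
    inclusion_counts: tuple[float, ...]       # one or two junction counts
    skipping_count: float
    group: str = ""

    @property
    def i_eff(self) -> float:
        return float(np.mean(self.inclusion_counts))

    @property
    def coverage(self) -> float:
        return self.i_eff + self.skipping_count

    @property
    def psi(self) -> float | None:
        return compute_psi(self.inclusion_counts, self.skipping_count)


@dataclass
class DiffSplicingResult:
    exon_id: str
    psi_a: float | None
    psi_b: float | None
    delta_psi: float | None
    p_value: float
    fdr: float | None = None
    flags: tuple[str, ...] = ()


def compute_psi(inclusion_counts, skipping_count: float, *,
                min_coverage: float = MIN_COVERAGE) -> float | None:
    """Junction-ratio Psi; None when effective coverage < min_coverage."""
    inc = np.atleast_1d(np.asarray(inclusion_counts, dtype=float))
    if (inc < 0).any() or skipping_count < 0:
        raise ValueError("junction counts must be nonnegative")
    i_eff = float(inc.mean())
    if i_eff + skipping_count < min_coverage:
        return None
    return i_eff / (i_eff + skipping_count)


def _pooled(records: list[PsiRecord]) -> tuple[float, float]:
    return (sum(r.i_eff for r in records),
            sum(r.skipping_count for r in records))


def diff_splicing(group_a: list[PsiRecord],
                  group_b: list[PsiRecord]) -> DiffSplicingResult:
    """Pooled two-sided Fisher exact test of inclusion vs skipping by group.

    Counts are pooled per group into a 2x2 table; the two-sided p-value
    follows the probability-mass rule (sum over tables no more probable
    than the observed one). Delta-Psi is the pooled-Psi difference A - B.
    """
    exon = group_a[0].exon_id if group_a else (
        group_b[0].exon_id if group_b else "")
    ia, sa = _pooled(group_a)
    ib, sb = _pooled(group_b)
    table = np.round([[ia, sa], [ib, sb]]).astype(int)
    flags = []
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        p = 1.0
        flags.append("empty_margin")
    else:
        p = float(sps.fisher_exact(table, alternative="two-sided")[1])
    psi_a = ia / (ia + sa) if ia + sa > 0 else None
    psi_b = ib / (ib + sb) if ib + sb > 0 else None
    dpsi = psi_a - psi_b if psi_a is not None and psi_b is not None else None
    return DiffSplicingResult(exon, psi_a, psi_b, dpsi, p, flags=tuple(flags))


def diff_splicing_table(records: list[PsiRecord], group_a: str,
                        group_b: str) -> list[DiffSplicingResult]:
    """Per-exon differential tests with BH adjustment across exons."""
    exons = sorted({r.exon_id for r in records})
    results = []
    for exon in exons:
        a = [r for r in records if r.exon_id == exon and r.group == group_a]
        b = [r for r in records if r.exon_id == exon and r.group == group_b]
        results.append(diff_splicing(a, b))
    fdrs = bh_fdr([r.p_value for r in results])
    for r, q in zip(results, fdrs):
        r.fdr = float(q)
    return results


def rtpcr_psi(inclusion_band: float, skipping_band: float, *,
              inclusion_len_bp: float | None = None,
              skipping_len_bp: float | None = None,
              molar_correct: bool = False) -> float:
    """Psi from gel band intensities, optionally molar-corrected.

    With ``molar_correct`` the intensities are divided by their amplicon
    lengths first (intensity scales with amplicon mass, molarity is what
    Psi measures).
    """
    if inclusion_band < 0 or skipping_band < 0:
        raise ValueError("band intensities must be nonnegative")
    if inclusion_band == 0 and skipping_band == 0:
        raise ValueError("both bands zero: Psi undefined")
    inc, skip = inclusion_band, skipping_band
    if molar_correct:
        if not inclusion_len_bp or not skipping_len_bp:
            raise ValueError("molar correction requires amplicon lengths")
        inc, skip = inc / inclusion_len_bp, skip / skipping_len_bp
    return inc / (inc + skip)


def peptide_length_aa(exon_length_nt: int) -> int:
    """Residues encoded by an in-frame cassette exon (length / 3)."""
    if exon_length_nt <= 0 or exon_length_nt % CODON_NT:
        raise ValueError("exon length must be a positive multiple of 3")
    return exon_length_nt // CODON_NT


# ---------------------------------------------------------------------
# TSV I/O: exon_id, sample_id, group, inc1, inc2, skip (inc2 may be NA)
# ---------------------------------------------------------------------

def read_counts_table(path) -> list[PsiRecord]:
    df = pd.read_csv(path, sep="\t")
    records = []
    for _, row in df.iterrows():
        inc = [float(row["inc1"])]
        if "inc2" in df.columns and pd.notna(row["inc2"]):
            inc.append(float(row["inc2"]))
        records.append(PsiRecord(exon_id=str(row["exon_id"]),
                                 sample_id=str(row["sample_id"]),
                                 inclusion_counts=tuple(inc),
                                 skipping_count=float(row["skip"]),
                                 group=str(row.get("group", ""))))
    return records


def write_psi_table(records: list[PsiRecord], path) -> pd.DataFrame:
    df = pd.DataFrame([{"exon_id": r.exon_id, "sample_id": r.sample_id,
                        "group": r.group, "coverage": r.coverage,
                        "psi": r.psi} for r in records])
    df.to_csv(path, sep="\t", index=False)
    return df


def write_diff_table(results: list[DiffSplicingResult], path) -> pd.DataFrame:
    df = pd.DataFrame([{"exon_id": r.exon_id, "psi_a": r.psi_a,
                        "psi_b": r.psi_b, "delta_psi": r.delta_psi,
                        "p": r.p_value, "fdr": r.fdr,
                        "flags": ";".join(r.flags)} for r in results])
    df.to_csv(path, sep="\t", index=False)
    return df
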