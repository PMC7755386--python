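"""Variants differing between two individuals, coded against a reference panel.

A "pairwise SNV" is a bi-allelic site at which the two individuals' unordered
diploid genotypes differ, i.e. their alternate-allele dosages differ. Each
such site is looked up in an independent reference frequency table (matching
chrom, pos, and alleles) and its geographic distribution code attached; sites
absent from the reference are counted separately (S_U) and treated as not
globally widespread.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .freqtable import FrequencyTable
from .geocode import CodeTally, EncodingConfig, encode_counts

logger = logging.getLogger(__name__)

#: tally key for pairwise variants absent from the reference table
UNOBSERVED = "unobserved"


def extract_pair(vcf_source, sample_a: str, sample_b: str) -> pd.DataFrame:
    """Read two samples' alt-allele dosages at every bi-allelic SNV.

    Returns a DataFrame with chrom, pos, ref, alt, dos_a, dos_b; dosages are
    NaN where a genotype is missing (including half-calls).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_source), samples=[sample_a, sample_b])
    if set(vcf.samples) != {sample_a, sample_b}:
        raise ValueError("requested samples not found in the VCF")
    ia, ib = vcf.samples.index(sample_a), vcf.samples.index(sample_b)
    rows = []
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            continue
        gt = rec.genotype.array()[:, :-1]

        def dosage(i: int) -> float:
            g = gt[i]
            return float((g == 1).sum()) if np.all(g >= 0) else np.nan

        rows.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0], dosage(ia), dosage(ib)))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "dos_a", "dos_b"])


def pairwise_sites(genotypes_a, genotypes_b=None) -> pd.DataFrame:
    """Sites where the two individuals' allele dosages differ.

    Accepts either the DataFrame from :func:`extract_pair` or two dosage
    arrays over the same site universe. Sites with a missing genotype in
    either individual are excluded (and logged), not counted as differences.
    """
    if isinstance(genotypes_a, pd.DataFrame):
        df = genotypes_a
        a = df["dos_a"].to_numpy(dtype=float)
        b = df["dos_b"].to_numpy(dtype=float)
    else:
        a = np.asarray(genotypes_a, dtype=float)
        b = np.asarray(genotypes_b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("the two individuals must share one site universe")
        df = pd.DataFrame({"dos_a": a, "dos_b": b})
    called = ~(np.isnan(a) | np.isnan(b))
    n_missing = int((~called).sum())
    if n_missing:
        logger.info("pairwise_sites: %d sites dropped for missing genotypes", n_missing)
    differ = called & (a != b)
    return df.loc[differ].reset_index(drop=True)


@dataclass(frozen=True)
class PairwiseResult:
    """Summary of the variants differing between one pair of individuals."""

    S: int
    S_U: int
    tally: CodeTally | None  # over coded variants plus the UNOBSERVED category
    widespread_fraction: float | None  # denominator S; unobserved counted as not widespread

    @property
    def degenerate(self) -> bool:
        return self.S == 0


def classify_pairwise(
    sites: pd.DataFrame,
    reference_table: FrequencyTable,
    config: EncodingConfig | None = None,
) -> PairwiseResult:
    """Attach reference codes to pairwise sites and summarise.

    Matching requires chrom, pos, ref and alt to agree with the reference
    table; unmatched sites (including allele mismatches) count toward S_U.
    The widespread fraction uses denominator S, so reference-unobserved
    variants are assumed not to be globally widespread.
    """
    config = config or EncodingConfig()
    S = len(sites)
    if S == 0:
        return PairwiseResult(S=0, S_U=0, tally=None, widespread_fraction=None)
    ref = reference_table.variants.copy()
    ref["__row"] = np.arange(len(ref))
    merged = sites.merge(
        ref[["chrom", "pos", "ref", "alt", "__row"]],
        on=["chrom", "pos", "ref", "alt"],
        how="left",
    )
    matched = merged["__row"].notna().to_numpy()
    S_U = int((~matched).sum())
    counts: dict[str, int] = {}
    if matched.any():
        rows = merged.loc[matched, "__row"].to_numpy(dtype=int)
        codes = encode_counts(
            reference_table.ac[rows], reference_table.an[rows], config.threshold
        )
        for c in codes:
            counts[c] = counts.get(c, 0) + 1
    n_widespread = sum(n for c, n in counts.items() if "u" not in c)
    if S_U:
        counts[UNOBSERVED] = S_U
    return PairwiseResult(
        S=S,
        S_U=S_U,
        tally=CodeTally(counts),
        widespread_fraction=n_widespread / S,
    )
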