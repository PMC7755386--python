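"""Per-group allele frequency tables from VCF genotypes.

This module turns a VCF of bi-allelic SNVs plus a sample->group panel into a
:class:`FrequencyTable`: one row per variant holding the count of the tracked
allele (globally minor by default, or derived) and the number of called
chromosomes in each group. Counts, not frequencies, are the primary
representation so that downstream rare/common threshold comparisons can be
made exactly on integers.
"""

from __future__ import annotations

import logging
from collections.abc import Iterator, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")

#: Example regional grouping sizes in the style of a global reference panel
#: with five continental-scale groups (diploid sample counts).
EXAMPLE_REGION_SIZES = {"AFR": 504, "EUR": 404, "SAS": 489, "EAS": 504, "AMR": 603}


@dataclass(frozen=True)
class GroupingScheme:
    """Ordered sample -> group mapping that fixes the code letter order.

    Parameters
    ----------
    sample_ids:
        All sample identifiers, in panel order.
    group_of:
        Map from sample id to its (single) group label.
    group_order:
        Ordered distinct group labels; the geographic code has one letter per
        entry, in this order.
    """

    sample_ids: tuple[str, ...]
    group_of: Mapping[str, str]
    group_order: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = pd.Series(self.sample_ids).value_counts()
            raise ValueError(
                f"duplicate sample ids in panel: {list(dupes[dupes > 1].index)[:5]}"
            )
        if len(set(self.group_order)) != len(self.group_order):
            raise ValueError("group_order contains duplicate labels")
        missing = [s for s in self.sample_ids if s not in self.group_of]
        if missing:
            raise ValueError(f"samples without a group assignment: {missing[:5]}")
        extra = set(self.group_of[s] for s in self.sample_ids) - set(self.group_order)
        if extra:
            raise ValueError(f"groups missing from group_order: {sorted(extra)}")
        for g in self.group_order:
            if self.n_diploid[g] == 0:
                raise ValueError(f"group {g!r} has no samples")

    @property
    def n_diploid(self) -> dict[str, int]:
        """Diploid sample count per group."""
        counts = dict.fromkeys(self.group_order, 0)
        for s in self.sample_ids:
            counts[self.group_of[s]] += 1
        return counts

    @property
    def n_groups(self) -> int:
        return len(self.group_order)

    def group_indices(self, samples: Sequence[str]) -> dict[str, np.ndarray]:
        """Indices of ``samples`` belonging to each group, in group order."""
        idx: dict[str, list[int]] = {g: [] for g in self.group_order}
        for i, s in enumerate(samples):
            if s not in self.group_of:
                raise ValueError(f"sample {s!r} is not in the grouping panel")
            idx[self.group_of[s]].append(i)
        return {g: np.asarray(v, dtype=int) for g, v in idx.items()}


def read_panel(
    panel_source,
    group_column: str = "group",
    sample_column: str = "sample",
    group_order: Sequence[str] | None = None,
) -> GroupingScheme:
    """Read a tab-separated panel file (or DataFrame) into a GroupingScheme.

    The panel must have a sample-id column and a group column. Group order is
    taken from ``group_order`` when supplied, otherwise from first appearance.
    """
    if isinstance(panel_source, pd.DataFrame):
        panel = panel_source
    else:
        panel = pd.read_csv(panel_source, sep="\t", dtype=str)
    for col in (sample_column, group_column):
        if col not in panel.columns:
            raise ValueError(f"panel is missing required column {col!r}")
    samples = panel[sample_column].tolist()
    groups = panel[group_column].tolist()
    if group_order is None:
        group_order = list(dict.fromkeys(groups))
    return GroupingScheme(
        sample_ids=tuple(samples),
        group_of=dict(zip(samples, groups)),
        group_order=tuple(group_order),
    )


def example_grouping(region_sizes: Mapping[str, int] | None = None) -> GroupingScheme:
    """Synthetic example grouping with five continental-style regions.

    Sample ids are generated (``AFR_0000`` ...); diploid counts default to
    :data:`EXAMPLE_REGION_SIZES`. Useful as a documented fixture for the
    five-letter coding examples.
    """
    sizes = dict(region_sizes or EXAMPLE_REGION_SIZES)
    sample_ids: list[str] = []
    group_of: dict[str, str] = {}
    for g, n in sizes.items():
        for i in range(n):
            sid = f"{g}_{i:04d}"
            sample_ids.append(sid)
            group_of[sid] = g
    return GroupingScheme(tuple(sample_ids), group_of, tuple(sizes))


@dataclass(frozen=True)
class VariantRecord:
    """A single bi-allelic SNV with per-group counts of the tracked allele."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    tracked_allele: str
    allele_counts: dict[str, int]
    chrom_counts: dict[str, int]
    tracked: str = "minor"  # or "derived"

    @property
    def global_count(self) -> int:
        return sum(self.allele_counts.values())

    @property
    def global_freq(self) -> float:
        return self.global_count / sum(self.chrom_counts.values())

    def freq(self, group: str) -> float:
        an = self.chrom_counts[group]
        return self.allele_counts[group] / an if an else 0.0


def is_singleton(variant: VariantRecord) -> bool:
    """True iff the tracked allele occurs exactly once in the whole sample.

    The definition is count-based: a single homozygous carrier (count 2) is
    not a singleton.
    """
    gc = variant.global_count
    if gc == 0:
        raise ValueError("variant with global count 0 violates the observed-variant invariant")
    return gc == 1


class FrequencyTable:
    """Per-variant, per-group counts and frequencies of the tracked allele.

    Columns (groups) are ordered by ``group_order``. ``ac`` and ``an`` are
    integer arrays of shape (n_variants, n_groups): tracked-allele count and
    called-chromosome count.
    """

    def __init__(
        self,
        variants: pd.DataFrame,
        ac: np.ndarray,
        an: np.ndarray,
        group_order: Sequence[str],
        grouping: GroupingScheme | None = None,
        tracked: str = "minor",
    ) -> None:
        ac = np.asarray(ac, dtype=np.int64)
        an = np.asarray(an, dtype=np.int64)
        if ac.shape != an.shape or ac.ndim != 2:
            raise ValueError("ac and an must be 2-D arrays of identical shape")
        if ac.shape[1] != len(group_order):
            raise ValueError("number of count columns must equal number of groups")
        if len(variants) != ac.shape[0]:
            raise ValueError("variant metadata and count arrays disagree in length")
        if np.any(ac < 0) or np.any(ac > an):
            raise ValueError("allele counts must satisfy 0 <= ac <= an per group")
        if np.any(ac.sum(axis=1) < 1):
            raise ValueError("every variant must be observed at least once")
        required = {"chrom", "pos", "ref", "alt", "tracked_allele"}
        if not required.issubset(variants.columns):
            raise ValueError(f"variant metadata needs columns {sorted(required)}")
        self.variants = variants.reset_index(drop=True)
        self.ac = ac
        self.an = an
        self.group_order = tuple(group_order)
        self.grouping = grouping
        self.tracked = tracked

    def __len__(self) -> int:
        return self.ac.shape[0]

    @property
    def freqs(self) -> np.ndarray:
        """Per-group frequency of the tracked allele; 0 where no calls."""
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(self.an > 0, self.ac / np.maximum(self.an, 1), 0.0)
        return f

    @property
    def global_count(self) -> np.ndarray:
        return self.ac.sum(axis=1)

    @property
    def global_freq(self) -> np.ndarray:
        return self.global_count / self.an.sum(axis=1)

    def singleton_mask(self) -> np.ndarray:
        return self.global_count == 1

    def record(self, i: int) -> VariantRecord:
        row = self.variants.iloc[i]
        return VariantRecord(
            chrom=str(row.chrom),
            pos=int(row.pos),
            ref=str(row.ref),
            alt=str(row.alt),
            tracked_allele=str(row.tracked_allele),
            allele_counts=dict(zip(self.group_order, self.ac[i].tolist())),
            chrom_counts=dict(zip(self.group_order, self.an[i].tolist())),
            tracked=self.tracked,
        )

    def __iter__(self) -> Iterator[VariantRecord]:
        return (self.record(i) for i in range(len(self)))

    def subset(self, mask: np.ndarray) -> "FrequencyTable":
        mask = np.asarray(mask)
        return FrequencyTable(
            self.variants.loc[mask].reset_index(drop=True),
            self.ac[mask],
            self.an[mask],
            self.group_order,
            grouping=self.grouping,
            tracked=self.tracked,
        )

    # -- tabular interchange -------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        df = self.variants.copy()
        df.columns = [c.upper() for c in df.columns]
        df = df.rename(columns={"TRACKED_ALLELE": "TRACKED"})
        df["GLOBAL_COUNT"] = self.global_count
        for j, g in enumerate(self.group_order):
            df[f"FREQ_{g}"] = self.freqs[:, j]
        for j, g in enumerate(self.group_order):
            df[f"AC_{g}"] = self.ac[:, j]
            df[f"AN_{g}"] = self.an[:, j]
        return df

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, grouping: GroupingScheme | None = None) -> "FrequencyTable":
        df = pd.read_csv(path, sep="\t")
        group_order = [c[3:] for c in df.columns if c.startswith("AC_")]
        if not group_order:
            raise ValueError("no AC_<group> columns found in frequency table")
        ac = df[[f"AC_{g}" for g in group_order]].to_numpy(dtype=np.int64)
        an = df[[f"AN_{g}" for g in group_order]].to_numpy(dtype=np.int64)
        meta = pd.DataFrame(
            {
                "chrom": df["CHROM"].astype(str),
                "pos": df["POS"].astype(int),
                "ref": df["REF"],
                "alt": df["ALT"],
                "tracked_allele": df["TRACKED"],
            }
        )
        return cls(meta, ac, an, group_order, grouping=grouping)


def _derived_allele(ref: str, alt: str, ancestral: str | None) -> str | None:
    """Return the derived allele, or None when the ancestral call is unusable."""
    if ancestral is None:
        return None
    aa = ancestral.strip().upper()
    if aa == ref:
        return alt
    if aa == alt:
        return ref
    return None


def vcf_to_freq_table(
    vcf_source,
    grouping: GroupingScheme,
    polarization: str = "minor",
    ancestral_annotations: Mapping[tuple[str, int], str] | str | None = "AA",
) -> FrequencyTable:
    """Read a VCF and compute per-group counts of the tracked allele.

    Multi-allelic records, non-SNVs, and sites monomorphic across all called
    genotypes are skipped (counted in the log). Missing genotype alleles are
    excluded from both numerator and denominator, so chromosome counts vary
    per site. With ``polarization="minor"`` the globally rarer allele is
    tracked (ties at exactly 50% track ALT); with ``"derived"`` the mutant
    allele is tracked using ancestral annotations, which may be an INFO key
    (default ``"AA"``) or a ``(chrom, pos) -> base`` mapping.
    """
    from cyvcf2 import VCF

    if polarization not in ("minor", "derived"):
        raise ValueError("polarization must be 'minor' or 'derived'")

    vcf = VCF(str(vcf_source), gts012=False)
    samples = list(vcf.samples)
    for s in samples:
        if s not in grouping.group_of:
            raise ValueError(f"VCF sample {s!r} missing from the grouping panel")
    gidx = grouping.group_indices(samples)
    order = grouping.group_order
    k = len(order)

    rows: list[tuple] = []
    ac_rows: list[np.ndarray] = []
    an_rows: list[np.ndarray] = []
    skipped = {"non_snv_or_multiallelic": 0, "monomorphic": 0, "no_ancestral": 0}

    for rec in vcf:
        if len(rec.ALT) != 1:
            skipped["non_snv_or_multiallelic"] += 1
            continue
        ref, alt = rec.REF.upper(), rec.ALT[0].upper()
        if ref not in _BASES or alt not in _BASES:
            skipped["non_snv_or_multiallelic"] += 1
            continue
        gt = rec.genotype.array()  # (n_samples, ploidy+1); last column is phase
        alleles = gt[:, :-1]
        called = alleles >= 0
        is_alt = (alleles == 1) & called
        alt_per_sample = is_alt.sum(axis=1)
        an_per_sample = called.sum(axis=1)

        alt_g = np.empty(k, dtype=np.int64)
        an_g = np.empty(k, dtype=np.int64)
        for j, g in enumerate(order):
            idx = gidx[g]
            alt_g[j] = alt_per_sample[idx].sum()
            an_g[j] = an_per_sample[idx].sum()
        alt_total, an_total = int(alt_g.sum()), int(an_g.sum())
        if an_total == 0 or alt_total == 0 or alt_total == an_total:
            skipped["monomorphic"] += 1
            continue

        if polarization == "minor":
            # tie at exactly 50% tracks ALT
            if 2 * alt_total > an_total:
                tracked_allele, ac_g = ref, an_g - alt_g
            else:
                tracked_allele, ac_g = alt, alt_g
        else:
            if isinstance(ancestral_annotations, Mapping):
                aa = ancestral_annotations.get((rec.CHROM, rec.POS))
            else:
                aa = rec.INFO.get(ancestral_annotations or "AA")
            derived = _derived_allele(ref, alt, aa)
            if derived is None:
                skipped["no_ancestral"] += 1
                continue
            tracked_allele = derived
            ac_g = alt_g if derived == alt else an_g - alt_g

        rows.append((rec.CHROM, rec.POS, ref, alt, tracked_allele))
        ac_rows.append(ac_g)
        an_rows.append(an_g)

    if any(skipped.values()):
        logger.info("vcf_to_freq_table skipped records: %s", skipped)

    meta = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "tracked_allele"])
    ac = np.vstack(ac_rows) if ac_rows else np.empty((0, k), dtype=np.int64)
    an = np.vstack(an_rows) if an_rows else np.empty((0, k), dtype=np.int64)
    return FrequencyTable(meta, ac, an, order, grouping=grouping, tracked=polarization)
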