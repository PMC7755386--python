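"""Synthetic genotype data with known ground-truth code structure.

Two generators: an archetype mixture (:func:`simulate_table`,
:func:`simulate_vcf`) whose per-variant codes hold by construction — the
oracle for encoder and pipeline tests — and a coalescent generator under the
two-population split model (:func:`simulate_split_dataset`) for end-to-end
comparison against the theory module. Genotypes are written from realized
allele counts, never re-sampled, so reading a simulated VCF back reproduces
the table exactly.
"""

from __future__ import annotations

import io
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from .freqtable import FrequencyTable, GroupingScheme
from .geocode import _as_fraction
from .theory import SplitModelParams

ARCHETYPES = (
    "private_singleton",
    "private_rare",
    "shared_rare_pair",
    "globally_common",
    "common_one_only",
)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimSpec:
    """Mixture specification for the archetype generator.

    ``group_sizes`` maps group label -> diploid sample count (insertion order
    fixes the code order); ``weights`` maps archetype -> mixture weight.
    """

    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {f"G{i+1}": 20 for i in range(5)}
    )
    n_variants: int = 1000
    weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "private_singleton": 0.35,
            "private_rare": 0.25,
            "shared_rare_pair": 0.15,
            "globally_common": 0.20,
            "common_one_only": 0.05,
        }
    )
    threshold: Fraction = Fraction(1, 20)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("all group sample sizes must be >= 1")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        unknown = set(self.weights) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes: {sorted(unknown)}")
        w = np.array([self.weights.get(a, 0.0) for a in ARCHETYPES])
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must be non-negative and sum to 1")
        object.__setattr__(self, "threshold", _as_fraction(self.threshold))

    @property
    def group_order(self) -> tuple[str, ...]:
        return tuple(self.group_sizes)

    def rare_cap(self, group: str) -> int:
        """Largest 'R' count in a group: floor(threshold * 2n)."""
        thr = self.threshold
        return (thr.numerator * 2 * self.group_sizes[group]) // thr.denominator

    def grouping(self) -> GroupingScheme:
        ids: list[str] = []
        group_of: dict[str, str] = {}
        for g, n in self.group_sizes.items():
            for i in range(n):
                s = f"{g}_{i:04d}"
                ids.append(s)
                group_of[s] = g
        return GroupingScheme(tuple(ids), group_of, self.group_order)


def _draw_counts(spec: SimSpec, archetype: str, rng: np.random.Generator) -> np.ndarray:
    order = spec.group_order
    k = len(order)
    two_n = np.array([2 * spec.group_sizes[g] for g in order])
    caps = np.array([spec.rare_cap(g) for g in order])
    ac = np.zeros(k, dtype=np.int64)

    if archetype in ("private_singleton", "private_rare", "common_one_only", "shared_rare_pair"):
        if archetype == "shared_rare_pair":
            targets = rng.choice(k, size=2, replace=False)
        else:
            targets = [int(rng.integers(k))]
    if archetype == "private_singleton":
        ac[targets[0]] = 1
    elif archetype == "private_rare":
        g = targets[0]
        if caps[g] < 1:
            raise ValueError("rare class empty: threshold * 2n < 1 for some group")
        ac[g] = rng.integers(1, caps[g] + 1)
    elif archetype == "shared_rare_pair":
        for g in targets:
            if caps[g] < 1:
                raise ValueError("rare class empty: threshold * 2n < 1 for some group")
            ac[g] = rng.integers(1, caps[g] + 1)
    elif archetype == "globally_common":
        for g in range(k):
            lo, hi = caps[g] + 1, two_n[g] // 2  # common, and per-group minor
            if lo > hi:
                raise ValueError("common class empty: threshold >= 0.5 for some group")
            ac[g] = rng.integers(lo, hi + 1)
    elif archetype == "common_one_only":
        g = targets[0]
        lo, hi = caps[g] + 1, two_n[g] // 2
        if lo > hi:
            raise ValueError("common class empty: threshold >= 0.5 for some group")
        ac[g] = rng.integers(lo, hi + 1)
    else:
        raise ValueError(f"unknown archetype {archetype!r}")
    return ac


def _true_code(ac: np.ndarray, spec: SimSpec) -> str:
    letters = []
    for j, g in enumerate(spec.group_order):
        if ac[j] == 0:
            letters.append("u")
        elif ac[j] <= spec.rare_cap(g):
            letters.append("R")
        else:
            letters.append("C")
    return "".join(letters)


def simulate_table(spec: SimSpec) -> tuple[FrequencyTable, pd.DataFrame]:
    """Draw a frequency table from the archetype mixture.

    Returns the table and a ground-truth frame (archetype, true_code) whose
    codes hold by construction; the tracked allele is always ALT.
    """
    rng = np.random.default_rng(spec.seed)
    order = spec.group_order
    two_n = np.array([2 * spec.group_sizes[g] for g in order])
    arch_idx = rng.choice(len(ARCHETYPES), size=spec.n_variants,
                          p=[spec.weights.get(a, 0.0) for a in ARCHETYPES])
    ac_rows, truth = [], []
    for a in arch_idx:
        archetype = ARCHETYPES[a]
        ac = _draw_counts(spec, archetype, rng)
        ac_rows.append(ac)
        truth.append((archetype, _true_code(ac, spec)))
    ac = np.vstack(ac_rows)
    an = np.tile(two_n, (spec.n_variants, 1))
    ref_alt = np.array([rng.choice(4, size=2, replace=False) for _ in range(spec.n_variants)])
    meta = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, spec.n_variants + 1),
            "ref": _BASES[ref_alt[:, 0]],
            "alt": _BASES[ref_alt[:, 1]],
        }
    )
    meta["tracked_allele"] = meta["alt"]
    table = FrequencyTable(meta, ac, an, order, grouping=spec.grouping(), tracked="minor")
    truth_df = pd.DataFrame(truth, columns=["archetype", "true_code"])
    return table, truth_df


def _genotype_strings(ac: int, two_n: int, rng: np.random.Generator) -> list[str]:
    """Unphased diploid GT strings carrying exactly ``ac`` ALT alleles."""
    alleles = np.zeros(two_n, dtype=int)
    alleles[rng.choice(two_n, size=ac, replace=False)] = 1
    return [f"{alleles[2*i]}/{alleles[2*i+1]}" for i in range(two_n // 2)]


def write_vcf(
    path,
    meta: pd.DataFrame,
    genotypes: Sequence[Sequence[str]],
    samples: Sequence[str],
    ancestral: Sequence[str] | None = None,
) -> None:
    """Write a minimal plain-text VCF v4.2 with GT fields (and optional AA INFO)."""
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    if ancestral is not None:
        buf.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
    for chrom in dict.fromkeys(meta["chrom"].astype(str)):
        buf.write(f"##contig=<ID={chrom}>\n")
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
    buf.write("\t".join(samples) + "\n")
    for i, row in enumerate(meta.itertuples(index=False)):
        info = f"AA={ancestral[i]}" if ancestral is not None else "."
        buf.write(
            f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t{info}\tGT\t"
            + "\t".join(genotypes[i])
            + "\n"
        )
    Path(path).write_text(buf.getvalue())


def write_panel(path, grouping: GroupingScheme) -> None:
    df = pd.DataFrame(
        {
            "sample": grouping.sample_ids,
            "pop": [grouping.group_of[s] for s in grouping.sample_ids],
            "group": [grouping.group_of[s] for s in grouping.sample_ids],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def simulate_vcf(spec: SimSpec, out_dir) -> tuple[Path, Path, pd.DataFrame]:
    """Simulate a table and write it as VCF + panel; returns paths and truth.

    Genotypes realize the table's exact allele counts (Hardy-Weinberg-style
    random placement of allele copies onto chromosomes), so reading the VCF
    back reproduces the counts identically. Output is byte-stable for a
    fixed seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table, truth = simulate_table(spec)
    rng = np.random.default_rng(spec.seed + 1)
    grouping = table.grouping
    order = table.group_order
    genotypes = []
    for i in range(len(table)):
        row = []
        for j, g in enumerate(order):
            row.extend(_genotype_strings(int(table.ac[i, j]), int(table.an[i, j]), rng))
        genotypes.append(row)
    vcf_path = out_dir / "simulated.vcf"
    panel_path = out_dir / "panel.tsv"
    write_vcf(vcf_path, table.variants, genotypes, grouping.sample_ids)
    write_panel(panel_path, grouping)
    truth_path = out_dir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return vcf_path, panel_path, truth


def simulate_split_dataset(
    params: SplitModelParams,
    n_sites: int,
    seed: int = 1,
    out_dir=None,
) -> tuple[Path, Path] | tuple[pd.DataFrame, np.ndarray, GroupingScheme]:
    """Coalescent genotypes for two populations under the split model.

    Simulates replicate genealogies with infinite-sites mutations until
    ``n_sites`` segregating sites are collected. The ancestral allele is the
    REF base, so derived-allele polarization is available through the AA
    INFO field. Writes VCF + panel into ``out_dir`` and returns the paths
    (or, with ``out_dir=None``, returns the site metadata, the genotype
    dosage matrix and the grouping without touching disk).
    """
    import msprime

    dem = msprime.Demography()
    dem.add_population(name="A", initial_size=params.N)
    dem.add_population(name="B", initial_size=params.N)
    dem.add_population(name="ANC", initial_size=params.N)
    if params.alpha > 0:
        dem.add_mass_migration(time=1e-6, source="A", dest="B", proportion=params.alpha)
        dem.add_mass_migration(time=2e-6, source="B", dest="A", proportion=params.alpha)
    dem.add_population_split(time=max(params.t_generations, 3e-6),
                             derived=["A", "B"], ancestral="ANC")

    n = params.n_sample
    base_seed = (int(seed) % (2**31 - 2)) + 1
    rows: list[np.ndarray] = []
    rep_iter = msprime.sim_ancestry(
        samples={"A": n, "B": n},
        demography=dem,
        num_replicates=10**7,  # bounded by the site-count break below
        random_seed=base_seed,
        ploidy=2,
    )
    # mutation rate chosen to yield a handful of sites per genealogy, keeping
    # within-tree clustering (shared genealogy) modest
    mut_rate = 0.1 / params.N
    for rep_no, ts in enumerate(rep_iter):
        mts = msprime.sim_mutations(
            ts,
            rate=mut_rate,
            random_seed=base_seed + rep_no + 1,
            model=msprime.BinaryMutationModel(),
            discrete_genome=False,
        )
        if mts.num_sites:
            g = mts.genotype_matrix()  # sites x haploid samples, 0/1
            rows.append(g)
        if sum(r.shape[0] for r in rows) >= n_sites:
            break
    gmat = np.vstack(rows)[:n_sites]

    ids = [f"A_{i:04d}" for i in range(n)] + [f"B_{i:04d}" for i in range(n)]
    grouping = GroupingScheme(
        tuple(ids), {s: s[0] for s in ids}, ("A", "B")
    )
    meta = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, n_sites + 1),
            "ref": "A",
            "alt": "C",
            "tracked_allele": "C",
        }
    )
    if out_dir is None:
        return meta, gmat, grouping

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genotypes = [
        [f"{row[2*i]}/{row[2*i+1]}" for i in range(len(ids))] for row in gmat
    ]
    vcf_path = out_dir / "split_model.vcf"
    panel_path = out_dir / "panel.tsv"
    write_vcf(vcf_path, meta, genotypes, ids, ancestral=["A"] * n_sites)
    write_panel(panel_path, grouping)
    return vcf_path, panel_path
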