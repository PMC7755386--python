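"""Geographic distribution codes: encoding, tallies, and table subsetting.

Each variant is summarised by a fixed-length string over {u, R, C}, one
letter per group in the grouping's order: 'u' if the tracked allele is
undetected in the group, 'R' (rare) if its frequency is positive but at most
the threshold, and 'C' (common) if strictly above the threshold. The
boundary is resolved on exact integer counts (``ac * q <= p * an`` for a
threshold p/q), never on floating-point frequencies.
"""

from __future__ import annotations

import logging
from collections import Counter
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .freqtable import FrequencyTable

logger = logging.getLogger(__name__)

ALPHABET = ("u", "R", "C")


def _as_fraction(threshold) -> Fraction:
    if isinstance(threshold, Fraction):
        thr = threshold
    elif isinstance(threshold, float):
        # decimal-string route so 0.05 means exactly 1/20
        thr = Fraction(repr(threshold))
    else:
        thr = Fraction(threshold)
    if not (0 < thr <= Fraction(1, 2)):
        raise ValueError("threshold must lie in (0, 0.5]")
    return thr


@dataclass(frozen=True)
class EncodingConfig:
    """Rare/common threshold (exact rational) plus optional group order."""

    threshold: Fraction = Fraction(1, 20)
    group_order: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "threshold", _as_fraction(self.threshold))


def count_possible_codes(k: int) -> int:
    """Number of possible codes for k groups: 3^k - 1 (all-'u' excluded)."""
    if k < 1:
        raise ValueError("number of groups must be >= 1")
    return 3**k - 1


def encode_variant(freqs: Sequence[float], config: EncodingConfig | None = None) -> str:
    """Encode one per-group frequency vector into a code string."""
    config = config or EncodingConfig()
    f = np.asarray(freqs, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    if not np.any(f > 0):
        raise ValueError("all-zero frequency vector: unobserved variant has no code")
    thr = float(config.threshold)
    return "".join("u" if x == 0 else ("R" if x <= thr else "C") for x in f)


def encode_counts(ac: np.ndarray, an: np.ndarray, threshold=Fraction(1, 20)) -> np.ndarray:
    """Vectorised exact encoding of count arrays into code strings.

    ``ac``/``an`` have one row per variant, one column per group. The letter
    is 'u' for ac == 0, 'R' for 0 < ac/an <= threshold, 'C' otherwise, with
    the comparison done on integers.
    """
    thr = _as_fraction(threshold)
    ac = np.asarray(ac, dtype=np.int64)
    an = np.asarray(an, dtype=np.int64)
    if ac.ndim == 1:
        ac, an = ac[None, :], an[None, :]
    if np.any(ac.sum(axis=1) < 1):
        raise ValueError("each variant must be observed at least once")
    rare = ac * thr.denominator <= thr.numerator * an
    letters = np.where(ac == 0, "u", np.where(rare, "R", "C"))
    return np.array(["".join(row) for row in letters])


def encode_table(table: FrequencyTable, config: EncodingConfig | None = None) -> np.ndarray:
    config = config or EncodingConfig()
    return encode_counts(table.ac, table.an, config.threshold)


class CodeTally:
    """Ranked multiset of geographic distribution codes.

    Rank order is by descending count with lexicographic tie-break, so plots
    and tables are reproducible.
    """

    def __init__(self, counts: dict[str, int]) -> None:
        if not counts:
            raise ValueError("empty tally")
        if any(c < 0 for c in counts.values()):
            raise ValueError("negative code count")
        self.counts = {str(c): int(n) for c, n in counts.items()}
        self.total = sum(counts.values())
        if self.total == 0:
            raise ValueError("tally with zero total")

    @classmethod
    def from_codes(cls, codes: Iterable[str]) -> "CodeTally":
        return cls(dict(Counter(codes)))

    @property
    def proportions(self) -> dict[str, float]:
        return {c: n / self.total for c, n in self.counts.items()}

    @property
    def rank_order(self) -> list[str]:
        return sorted(self.counts, key=lambda c: (-self.counts[c], c))

    def to_dataframe(self) -> pd.DataFrame:
        order = self.rank_order
        return pd.DataFrame(
            {
                "code": order,
                "count": [self.counts[c] for c in order],
                "proportion": [self.counts[c] / self.total for c in order],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CodeTally":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["code"], df["count"])))

    def __eq__(self, other) -> bool:
        return isinstance(other, CodeTally) and self.counts == other.counts

    def __repr__(self) -> str:
        top = ", ".join(f"{c}:{self.counts[c]}" for c in self.rank_order[:4])
        return f"CodeTally(total={self.total}, top=[{top}])"


def tally_codes(
    table: FrequencyTable,
    config: EncodingConfig | None = None,
    drop_singletons: bool = False,
) -> CodeTally:
    """Tally geographic distribution codes over a frequency table."""
    if len(table) == 0:
        raise ValueError("cannot tally an empty frequency table")
    if drop_singletons:
        table = table.subset(~table.singleton_mask())
        if len(table) == 0:
            raise ValueError("no variants left after removing singletons")
    return CodeTally.from_codes(encode_table(table, config))


def widespread_fraction(
    tally: CodeTally,
    scope: str = "common_in_any",
    qualifying_groups: Sequence[int] | None = None,
) -> float:
    """Fraction of variants found in every group (code without any 'u').

    ``scope`` sets the denominator: ``"all"`` uses every variant;
    ``"common_in_any"`` restricts to variants common ('C') in at least one
    group; ``"common_in_any_of"`` restricts to variants common in at least
    one of the group *positions* listed in ``qualifying_groups`` (e.g. the
    non-reference regions).
    """
    num = 0
    den = 0
    for code, n in tally.counts.items():
        if scope == "all":
            qualifies = True
        elif scope == "common_in_any":
            qualifies = "C" in code
        elif scope == "common_in_any_of":
            if qualifying_groups is None:
                raise ValueError("scope 'common_in_any_of' needs qualifying_groups")
            qualifies = any(code[i] == "C" for i in qualifying_groups)
        else:
            raise ValueError(f"unknown scope {scope!r}")
        if qualifies:
            den += n
            if "u" not in code:
                num += n
    if den == 0:
        raise ValueError("empty denominator: no variant qualifies under this scope")
    return num / den


def read_site_list(path, fmt: str = "auto") -> pd.DataFrame:
    """Read a site list as (chrom, pos) with 1-based positions.

    ``fmt="bed"`` expects 0-based half-open intervals, expanded to the
    covered 1-based positions; ``fmt="positions"`` expects two columns of
    chrom and 1-based position. ``"auto"`` picks BED for ``.bed`` paths.
    """
    if fmt == "auto":
        fmt = "bed" if str(path).endswith(".bed") else "positions"
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if fmt == "bed":
        chroms: list[str] = []
        positions: list[int] = []
        for _, row in df.iterrows():
            start, end = int(row[1]), int(row[2])
            for p in range(start + 1, end + 1):  # half-open 0-based -> 1-based
                chroms.append(str(row[0]))
                positions.append(p)
        return pd.DataFrame({"chrom": chroms, "pos": positions})
    if fmt == "positions":
        return pd.DataFrame({"chrom": df[0].astype(str), "pos": df[1].astype(int)})
    raise ValueError(f"unknown site-list format {fmt!r}")


def subset_to_sites(
    table: FrequencyTable,
    site_list,
    match_alleles: bool = False,
) -> FrequencyTable:
    """Restrict a table to sites in a list, preserving row order.

    ``site_list`` is an iterable of (chrom, pos) pairs, optionally
    (chrom, pos, ref, alt) when ``match_alleles`` is set, or a DataFrame with
    those columns. Positions are 1-based as in the VCF. Sites in the list but
    absent from the table are logged, not an error.
    """
    if isinstance(site_list, pd.DataFrame):
        if match_alleles:
            wanted = set(
                zip(site_list["chrom"].astype(str), site_list["pos"].astype(int),
                    site_list["ref"], site_list["alt"])
            )
        else:
            wanted = set(zip(site_list["chrom"].astype(str), site_list["pos"].astype(int)))
    else:
        wanted = {tuple(s) for s in site_list}
    v = table.variants
    if match_alleles:
        keys = list(zip(v["chrom"].astype(str), v["pos"].astype(int), v["ref"], v["alt"]))
    else:
        keys = list(zip(v["chrom"].astype(str), v["pos"].astype(int)))
    mask = np.array([k in wanted for k in keys], dtype=bool)
    n_missing = len(wanted) - len({k for k in keys if k in wanted})
    if n_missing:
        logger.info("subset_to_sites: %d listed sites absent from the table", n_missing)
    return table.subset(mask)
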