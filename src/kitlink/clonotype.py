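"""TCR clonotype calling and clone-frequency tiering.

Clones are defined by exact nucleotide identity of the paired α/β CDR3:
cells sharing both sequences belong to one clonotype.  Clonotypes are
placed in four frequency tiers — unique (1 cell), shared (2–4 cells),
moderate (>4 cells, below the high threshold) and high-frequency (at or
above the top-quartile threshold: the smallest observed clone size such
that cells in clones at least that large make up no more than 25% of the
repertoire).
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import TcrContig

TIERS = ["unique", "shared", "moderate", "high"]

#: lower bound of the moderate tier (">4 T cells sharing a TCR"); the high
#: threshold can never undercut it.
MODERATE_MIN = 5


@dataclass
class Clonotype:
    key: tuple[str, str]  # (TRA cdr3_nt, TRB cdr3_nt)
    members: list[str]
    tier: str | None = None

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class TierThreshold:
    high_threshold: float  # math.inf when no clone qualifies
    quartile_basis: str = "cell_weighted"


@dataclass
class PairFilterReport:
    """Exclusion tallies from productive-pair filtering."""

    kept: int = 0
    excluded: dict[str, int] = field(
        default_factory=lambda: {"no_alpha": 0, "no_beta": 0,
                                 "multi_alpha": 0, "multi_beta": 0})


def filter_productive_pairs(
    contigs: list[TcrContig],
) -> tuple[dict[str, tuple[str, str]], PairFilterReport]:
    """Keep barcodes with exactly one productive TRA and one productive TRB.

    Nonproductive contigs are discarded before the exactly-one rule is
    applied, so a cell with one productive pair plus a nonproductive extra
    chain is retained.
    """
    by_barcode: dict[str, dict[str, list[str]]] = defaultdict(
        lambda: {"TRA": [], "TRB": []})
    for c in contigs:
        if c.productive and c.chain in ("TRA", "TRB"):
            by_barcode[c.barcode][c.chain].append(c.cdr3_nt)

    pairs: dict[str, tuple[str, str]] = {}
    report = PairFilterReport()
    for bc, chains in by_barcode.items():
        n_a, n_b = len(chains["TRA"]), len(chains["TRB"])
        if n_a == 1 and n_b == 1:
            pairs[bc] = (chains["TRA"][0], chains["TRB"][0])
            report.kept += 1
        elif n_a == 0:
            report.excluded["no_alpha"] += 1
        elif n_b == 0:
            report.excluded["no_beta"] += 1
        elif n_a > 1:
            report.excluded["multi_alpha"] += 1
        else:
            report.excluded["multi_beta"] += 1
    return pairs, report


def call_clonotypes(pairs: dict[str, tuple[str, str]]) -> list[Clonotype]:
    """Partition barcodes by exact (α, β) nucleotide CDR3 identity."""
    groups: dict[tuple[str, str], list[str]] = defaultdict(list)
    for bc, key in pairs.items():
        groups[key].append(bc)
    # deterministic order: largest first, then key
    clones = [Clonotype(key=k, members=sorted(v)) for k, v in groups.items()]
    clones.sort(key=lambda c: (-c.size, c.key))
    return clones


def compute_high_threshold(
    clonotypes: list[Clonotype] | list[int],
    basis: str = "cell_weighted",
    quartile: float = 0.25,
) -> TierThreshold:
    """Top-quartile high-frequency threshold over the clone-size distribution.

    cell_weighted (default): cumulate cells from the largest clone size
    downwards; the threshold is the smallest observed size at which the
    cumulated cells still comprise ≤ ``quartile`` of all cells.
    clone_weighted: the 75th percentile of clone sizes.
    """
    sizes = [c.size if isinstance(c, Clonotype) else int(c) for c in clonotypes]
    if not sizes:
        raise ValueError("no clonotypes")
    if basis == "clone_weighted":
        thr = float(np.quantile(sizes, 1.0 - quartile))
        thr = max(math.ceil(thr), MODERATE_MIN)
        if max(sizes) < thr:
            return TierThreshold(math.inf, basis)
        return TierThreshold(thr, basis)
    if basis != "cell_weighted":
        raise ValueError(f"unknown basis {basis!r}")

    total = sum(sizes)
    by_size = Counter(sizes)
    cum = 0
    thr: float = math.inf
    for size in sorted(by_size, reverse=True):
        cum += size * by_size[size]
        if cum / total <= quartile:
            thr = size
        else:
            break
    if math.isinf(thr):
        return TierThreshold(math.inf, basis)
    return TierThreshold(max(thr, MODERATE_MIN), basis)


def tier_for_size(size: int, high_threshold: float) -> str:
    """unique ⇔ 1; shared ⇔ 2–4; moderate ⇔ >4 below threshold; high ⇔ ≥ threshold."""
    if size >= high_threshold:
        return "high"
    if size == 1:
        return "unique"
    if size <= 4:
        return "shared"
    return "moderate"


def assign_tiers(clonotypes: list[Clonotype],
                 t: TierThreshold) -> list[Clonotype]:
    for c in clonotypes:
        c.tier = tier_for_size(c.size, t.high_threshold)
    return clonotypes


def clonotype_table(clonotypes: list[Clonotype],
                    sample: str = "cohort") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "clone_id": [f"clone{i:05d}" for i in range(len(clonotypes))],
            "cdr3_nt_a": [c.key[0] for c in clonotypes],
            "cdr3_nt_b": [c.key[1] for c in clonotypes],
            "size": [c.size for c in clonotypes],
            "tier": [c.tier for c in clonotypes],
            "sample": sample,
        }
    )


def cell_tier_table(clonotypes: list[Clonotype]) -> pd.DataFrame:
    """Per-cell tier assignment (one row per retained barcode)."""
    rows = [(bc, f"clone{i:05d}", c.tier, c.size)
            for i, c in enumerate(clonotypes) for bc in c.members]
    return pd.DataFrame(rows, columns=["barcode", "clone_id", "tier",
                                       "clone_size"]).set_index("barcode")


def run_clonotyping(
    contigs: list[TcrContig],
    basis: str = "cell_weighted",
) -> tuple[list[Clonotype], TierThreshold, PairFilterReport]:
    """Filter → call → threshold → tier, in one step."""
    pairs, report = filter_productive_pairs(contigs)
    clones = call_clonotypes(pairs)
    thr = compute_high_threshold(clones, basis=basis)
    assign_tiers(clones, thr)
    return clones, thr, report
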