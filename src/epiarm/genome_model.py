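"""Genome model: markers, chromosome arms, and the combinatorics of arm tests.

This module owns the tabular inputs of an arm-level epistasis scan — the
marker map, centromere interval table, genotype matrix and phenotype table —
and the two structural operations built on them: assigning markers to
chromosome arms (short "S" vs long "L", split at the centromere interval)
and enumerating the chromosome-arm pairs and homeologous triplets that an
allopolyploid scan will test.

Coordinates are 1-based inclusive base pairs throughout, matching common
marker-map and VCF conventions.  Positions falling inside the centromere
interval (closed on both ends) are flagged ``in_centromere`` and belong to
no arm.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMap",
    "CentromereTable",
    "GenotypeMatrix",
    "ArmLabel",
    "PairEnumeration",
    "MissingCentromereError",
    "DEFAULT_ARM_PATTERN",
    "read_marker_map",
    "read_centromere_table",
    "read_phenotype_table",
    "read_genotype_tsv",
    "read_genotype_vcf",
    "write_genotype_vcf",
    "assign_arms",
    "arm_marker_sets",
    "parse_arm_label",
    "enumerate_arm_pairs",
    "enumerate_homeolog_triplets",
    "count_pairwise_tests",
]

#: arm labels such as "4BL": homeolog group "4", subgenome "B", long arm.
DEFAULT_ARM_PATTERN = r"^(?P<group>\d+)(?P<subgenome>[A-Za-z])(?P<letter>[SL])$"


class MissingCentromereError(KeyError):
    """A chromosome present in the marker map has no centromere interval."""


@dataclass(frozen=True)
class MarkerMap:
    """Physical marker map: marker id, chromosome and bp position (1-based)."""

    table: pd.DataFrame  # columns: marker_id, chromosome, position

    def __post_init__(self) -> None:
        required = {"marker_id", "chromosome", "position"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"marker map missing columns: {sorted(missing)}")
        if self.table["marker_id"].duplicated().any():
            dups = self.table.loc[self.table["marker_id"].duplicated(), "marker_id"]
            raise ValueError(f"duplicate marker ids: {list(dups.unique())[:5]}")
        if (self.table["position"] < 1).any():
            raise ValueError("marker positions must be >= 1 (1-based bp)")

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.table["chromosome"].unique())

    def positions(self, chromosome: str) -> np.ndarray:
        sel = self.table[self.table["chromosome"] == chromosome]
        return np.sort(sel["position"].to_numpy())


@dataclass(frozen=True)
class CentromereTable:
    """One centromere interval per chromosome; ``source`` is 'annotated' or 'estimated'."""

    table: pd.DataFrame  # columns: chromosome, start, end, source

    def __post_init__(self) -> None:
        required = {"chromosome", "start", "end"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"centromere table missing columns: {sorted(missing)}")
        if "source" not in self.table.columns:
            self.table["source"] = "annotated"
        if (self.table["start"] > self.table["end"]).any():
            raise ValueError("centromere start must be <= end")
        if self.table["chromosome"].duplicated().any():
            raise ValueError("more than one centromere row for a chromosome")

    def interval(self, chromosome: str) -> tuple[int, int]:
        sel = self.table[self.table["chromosome"] == chromosome]
        if sel.empty:
            raise MissingCentromereError(
                f"no centromere interval for chromosome {chromosome!r}; "
                f"add an annotated row or estimate one from marker density"
            )
        row = sel.iloc[0]
        return int(row["start"]), int(row["end"])

    def with_row(self, chromosome: str, start: int, end: int, source: str = "estimated") -> "CentromereTable":
        new = pd.concat(
            [
                self.table[self.table["chromosome"] != chromosome],
                pd.DataFrame(
                    [{"chromosome": chromosome, "start": int(start), "end": int(end), "source": source}]
                ),
            ],
            ignore_index=True,
        )
        return CentromereTable(new.sort_values("chromosome").reset_index(drop=True))


@dataclass
class GenotypeMatrix:
    """Lines x markers dosage matrix, coded 0/1/2 copies of the counted allele.

    Missing calls are ``NaN``; imputation is deferred to kinship construction.
    """

    lines: list[str]
    markers: list[str]
    calls: np.ndarray  # float array, shape (n_lines, n_markers), NaN = missing

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.lines), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.lines)} lines x {len(self.markers)} markers"
            )
        if len(set(self.lines)) != len(self.lines):
            raise ValueError("duplicate line ids")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("duplicate marker ids")
        finite = self.calls[np.isfinite(self.calls)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            bad = np.unique(finite[~np.isin(finite, (0.0, 1.0, 2.0))])
            raise ValueError(f"genotype calls must be 0/1/2 or missing; found {bad[:5]}")

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_index(self, marker_ids: Sequence[str]) -> np.ndarray:
        lookup = {m: j for j, m in enumerate(self.markers)}
        try:
            return np.array([lookup[m] for m in marker_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown marker id {exc.args[0]!r}") from None


# ---------------------------------------------------------------------------
# readers / writers (headered TSV; VCF via cyvcf2)
# ---------------------------------------------------------------------------

def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={"chromosome": str})


def read_marker_map(path) -> MarkerMap:
    return MarkerMap(_read_tsv(path)[["marker_id", "chromosome", "position"]])


def read_centromere_table(path) -> CentromereTable:
    df = _read_tsv(path)
    cols = ["chromosome", "start", "end"] + (["source"] if "source" in df.columns else [])
    return CentromereTable(df[cols])


def read_phenotype_table(path, lines: Iterable[str] | None = None) -> pd.DataFrame:
    """Read a long-format phenotype TSV with columns line_id, env_id, value."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"line_id": str, "env_id": str})
    return validate_phenotypes(df, lines)


def validate_phenotypes(df: pd.DataFrame, lines: Iterable[str] | None = None) -> pd.DataFrame:
    required = {"line_id", "env_id", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["line_id", "env_id"])
    if dup.any():
        first = df.loc[dup, ["line_id", "env_id"]].iloc[0]
        raise ValueError(
            f"duplicated (line, environment) observation: "
            f"({first['line_id']}, {first['env_id']})"
        )
    if lines is not None:
        unknown = set(df["line_id"]) - set(lines)
        if unknown:
            raise ValueError(f"phenotyped lines absent from genotype matrix: {sorted(unknown)[:5]}")
    return df.reset_index(drop=True)


def read_genotype_tsv(path) -> GenotypeMatrix:
    """Read a genotype matrix TSV: rows = lines, columns = markers, first column line_id."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return GenotypeMatrix(
        lines=[str(i) for i in df.index],
        markers=[str(c) for c in df.columns],
        calls=df.to_numpy(dtype=float),
    )


def read_genotype_vcf(path) -> GenotypeMatrix:
    """Read biallelic sites from a VCF; dosage counts the ALT allele."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    lines = list(vcf.samples)
    markers: list[str] = []
    cols: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"multi-allelic site not supported: {var.ID or var.POS}")
        markers.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
        dos = np.full(len(lines), np.nan)
        for i, gt in enumerate(var.genotypes):
            a, b = gt[0], gt[1]
            if a >= 0 and b >= 0:
                dos[i] = a + b
        cols.append(dos)
    vcf.close()
    calls = np.column_stack(cols) if cols else np.empty((len(lines), 0))
    return GenotypeMatrix(lines=lines, markers=markers, calls=calls)


def write_genotype_vcf(path, geno: GenotypeMatrix, marker_map: MarkerMap) -> None:
    """Write a minimal biallelic VCF (GT only) for the given genotype matrix."""
    pos = marker_map.table.set_index("marker_id")
    gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=epiarm\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in sorted(pos["chromosome"].unique()):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(geno.lines) + "\n")
        order = pos.loc[geno.markers].reset_index()
        order = order.sort_values(["chromosome", "position"], kind="stable")
        for _, row in order.iterrows():
            j = geno.markers.index(row["marker_id"])
            calls = [
                gt_codes.get(c, "./.") if np.isfinite(c) else "./."
                for c in geno.calls[:, j]
            ]
            fh.write(
                f"{row['chromosome']}\t{int(row['position'])}\t{row['marker_id']}"
                f"\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


# ---------------------------------------------------------------------------
# arm assignment
# ---------------------------------------------------------------------------

def assign_arms(marker_map: MarkerMap, centromeres: CentromereTable) -> pd.DataFrame:
    """Assign each marker to a chromosome arm, splitting at the centromere.

    Positions strictly below the interval go to the short arm ("S"), strictly
    above to the long arm ("L"); positions inside the closed interval are
    centromeric and belong to no arm.

    Returns a DataFrame with columns ``marker_id``, ``chromosome``, ``arm``
    (None for centromeric markers) and ``in_centromere``.
    """
    for chrom in marker_map.chromosomes:
        centromeres.interval(chrom)  # raises MissingCentromereError with the name

    records = []
    for _, row in marker_map.table.iterrows():
        chrom = row["chromosome"]
        start, end = centromeres.interval(chrom)
        p = int(row["position"])
        if p < start:
            arm, cen = f"{chrom}S", False
        elif p > end:
            arm, cen = f"{chrom}L", False
        else:
            arm, cen = None, True
        records.append(
            {"marker_id": row["marker_id"], "chromosome": chrom, "arm": arm, "in_centromere": cen}
        )
    return pd.DataFrame.from_records(records)


def arm_marker_sets(assignment: pd.DataFrame) -> dict[str, list[str]]:
    """Marker ids per arm label, excluding centromeric markers."""
    out: dict[str, list[str]] = {}
    sel = assignment[~assignment["in_centromere"]]
    for arm, sub in sel.groupby("arm"):
        out[str(arm)] = list(sub["marker_id"])
    return out


# ---------------------------------------------------------------------------
# arm-pair / triplet combinatorics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArmLabel:
    """Parsed arm label: homeolog group, subgenome, and arm letter (S/L)."""

    group: str
    subgenome: str
    letter: str

    @property
    def label(self) -> str:
        return f"{self.group}{self.subgenome}{self.letter}"


def parse_arm_label(label: str, pattern: str = DEFAULT_ARM_PATTERN) -> ArmLabel:
    m = re.match(pattern, label)
    if m is None:
        raise ValueError(f"arm label {label!r} does not match pattern {pattern!r}")
    d = m.groupdict()
    return ArmLabel(group=d["group"], subgenome=d["subgenome"], letter=d["letter"])


def classify_pair(a: ArmLabel, b: ArmLabel) -> str:
    """Classify an unordered arm pair as homeologous / within / across subgenome."""
    if a.subgenome == b.subgenome:
        return "within"
    if a.group == b.group and a.letter == b.letter:
        return "homeologous"
    return "across"


@dataclass
class PairEnumeration:
    """All unordered arm pairs with their class, plus class counts."""

    pairs: list[tuple[str, str, str]]  # (arm_i, arm_j, class)
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return len(self.pairs)

    def of_class(self, cls: str) -> list[tuple[str, str]]:
        return [(a, b) for a, b, c in self.pairs if c == cls]


def enumerate_arm_pairs(arms: Sequence[str], pattern: str = DEFAULT_ARM_PATTERN) -> PairEnumeration:
    """Enumerate and classify all unordered pairs of chromosome arms.

    Homeologous pairs share the homeolog group and arm letter but differ in
    subgenome; within-subgenome pairs share the subgenome; every remaining
    pair is across-subgenome.
    """
    parsed = {a: parse_arm_label(a, pattern) for a in arms}
    ordered = sorted(set(arms))
    pairs = [
        (a, b, classify_pair(parsed[a], parsed[b]))
        for a, b in itertools.combinations(ordered, 2)
    ]
    counts = {"homeologous": 0, "within": 0, "across": 0}
    for _, _, c in pairs:
        counts[c] += 1
    return PairEnumeration(pairs=pairs, counts=counts)


def enumerate_homeolog_triplets(
    arms: Sequence[str], pattern: str = DEFAULT_ARM_PATTERN
) -> tuple[list[tuple[str, str, str]], int]:
    """One triplet per (homeolog group, arm letter) spanning three subgenomes.

    Returns the homeologous triplets and, for context, the total number of
    unordered arm triplets C(n_arms, 3).
    """
    parsed = [parse_arm_label(a, pattern) for a in sorted(set(arms))]
    by_key: dict[tuple[str, str], list[ArmLabel]] = {}
    for a in parsed:
        by_key.setdefault((a.group, a.letter), []).append(a)
    triplets = []
    for key in sorted(by_key):
        members = by_key[key]
        if len({m.subgenome for m in members}) == 3:
            trip = tuple(sorted(m.label for m in members))
            triplets.append(trip)  # type: ignore[arg-type]
    n = len(set(a.label for a in parsed))
    total = n * (n - 1) * (n - 2) // 6
    return triplets, total


def count_pairwise_tests(m: int) -> int:
    """Number of pairwise interaction tests for m markers: m(m-1)/2."""
    if m < 2:
        raise ValueError(f"need at least 2 markers to form a pair, got {m}")
    return m * (m - 1) // 2
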