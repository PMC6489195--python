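"""Core data types and file I/O shared by every pipeline stage.

The package works on biallelic SNP genotypes coded as counts of the
counted (alternate) allele: 0, 1 or 2 copies per individual, with a
dedicated missing sentinel.  Genotypes travel together with per-SNP
fragment (clone) identifiers — several SNPs called on one restriction
fragment are tightly linked, which the QC stage exploits — and
per-individual population labels (river of origin) plus an optional
hatchery label.

All statistics in the package access genotypes through missing-aware
masks; the sentinel itself is never averaged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "AlleleFrequencies",
    "Pedigree",
    "PopulationSpec",
    "SimConfig",
    "GenotypeValidationError",
    "GenotypeParseError",
    "PedigreeValidationError",
    "read_genotypes",
    "write_genotypes",
    "read_pedigree",
    "write_pedigree",
    "write_run_report",
]

log = logging.getLogger("founderpop")

#: Sentinel for a missing call in ``GenotypeMatrix.calls``.  Code must not
#: average raw calls directly; use :meth:`GenotypeMatrix.masked_calls`.
MISSING: int = -9

_UNKNOWN_PARENT = "0"


class GenotypeValidationError(ValueError):
    """A genotype table violates the documented invariants."""


class GenotypeParseError(ValueError):
    """A genotype file could not be parsed; message names line/column."""


class PedigreeValidationError(ValueError):
    """A pedigree violates acyclicity or identifier constraints."""


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs allele-count table with metadata.

    Parameters
    ----------
    individual_ids, snp_ids
        Unique identifiers for rows and columns of ``calls``.
    fragment_ids
        Per-SNP fragment/clone identifier; several SNPs may share one.
    populations
        Per-individual population (river) label.
    hatcheries
        Optional per-individual hatchery label ("" when unknown).
    calls
        ``(n_individuals, n_snps)`` integer array with entries in
        ``{0, 1, 2, MISSING}``.
    """

    individual_ids: list[str]
    snp_ids: list[str]
    fragment_ids: list[str]
    populations: list[str]
    calls: np.ndarray
    hatcheries: list[str] | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int16)
        n_ind, n_snp = len(self.individual_ids), len(self.snp_ids)
        if self.calls.shape != (n_ind, n_snp):
            raise GenotypeValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{n_ind} individuals x {n_snp} SNPs"
            )
        if len(set(self.individual_ids)) != n_ind:
            raise GenotypeValidationError("duplicate individual ids")
        if len(set(self.snp_ids)) != n_snp:
            raise GenotypeValidationError("duplicate SNP ids")
        if len(self.fragment_ids) != n_snp:
            raise GenotypeValidationError("fragment_ids length mismatch")
        if len(self.populations) != n_ind:
            raise GenotypeValidationError("populations length mismatch")
        if self.hatcheries is None:
            self.hatcheries = [""] * n_ind
        elif len(self.hatcheries) != n_ind:
            raise GenotypeValidationError("hatcheries length mismatch")
        ok = np.isin(self.calls, (0, 1, 2, MISSING))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise GenotypeValidationError(
                f"invalid call {self.calls[i, j]} at individual "
                f"{self.individual_ids[i]!r}, SNP {self.snp_ids[j]!r}"
            )

    # -- shape & masks ---------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def missing_mask(self) -> np.ndarray:
        """Boolean array, True where the call is missing."""
        return self.calls == MISSING

    def masked_calls(self) -> np.ma.MaskedArray:
        """Calls as a masked array; the only sanctioned way to average."""
        return np.ma.masked_array(self.calls, mask=self.missing_mask())

    def missing_rate(self) -> float:
        if self.calls.size == 0:
            return 0.0
        return float(self.missing_mask().mean())

    # -- subsetting ------------------------------------------------------

    def _ind_indices(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.individual_ids)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown individual id {e.args[0]!r}") from None

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self._ind_indices(ids)
        return replace(
            self,
            individual_ids=[self.individual_ids[i] for i in idx],
            populations=[self.populations[i] for i in idx],
            hatcheries=[self.hatcheries[i] for i in idx],
            calls=self.calls[idx, :],
        )

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        lookup = {v: j for j, v in enumerate(self.snp_ids)}
        idx = np.array([lookup[s] for s in snp_ids], dtype=int)
        return replace(
            self,
            snp_ids=[self.snp_ids[j] for j in idx],
            fragment_ids=[self.fragment_ids[j] for j in idx],
            calls=self.calls[:, idx],
        )

    def population_labels(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def individuals_of(self, population: str) -> list[str]:
        return [
            i for i, p in zip(self.individual_ids, self.populations) if p == population
        ]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individual_ids == other.individual_ids
            and self.snp_ids == other.snp_ids
            and self.fragment_ids == other.fragment_ids
            and self.populations == other.populations
            and self.hatcheries == other.hatcheries
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class AlleleFrequencies:
    """Per-SNP frequency of the counted allele with its provenance.

    ``source_individuals`` records which individuals the estimate came
    from — the de-biasing pass cares about exactly this distinction.
    """

    snp_ids: list[str]
    p: np.ndarray
    source_individuals: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (len(self.snp_ids),):
            raise GenotypeValidationError("frequency vector length mismatch")
        if self.p.size and (np.nanmin(self.p) < 0 or np.nanmax(self.p) > 1):
            raise GenotypeValidationError("allele frequencies outside [0, 1]")


@dataclass
class Pedigree:
    """Parent assignments, possibly to ungenotyped dummy parents.

    Each record is ``(individual, sire, dam)`` with ``"0"`` meaning
    unknown.  ``dummy_parents`` flags placeholder parents invented to
    encode sibship rather than observed animals.
    """

    records: list[tuple[str, str, str]]
    dummy_parents: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            raise PedigreeValidationError("duplicate individual ids in pedigree")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        parents = {r[0]: {p for p in r[1:] if p != _UNKNOWN_PARENT} for r in self.records}
        for ind, ps in parents.items():
            if ind in ps:
                raise PedigreeValidationError(f"{ind!r} is its own parent")
        # iterative DFS over the child -> parent relation
        WHITE, GREY, BLACK = 0, 1, 2
        colour: dict[str, int] = {}
        for start in parents:
            if colour.get(start, WHITE) != WHITE:
                continue
            stack: list[tuple[str, bool]] = [(start, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    colour[node] = BLACK
                    continue
                if colour.get(node, WHITE) == GREY:
                    continue
                colour[node] = GREY
                stack.append((node, True))
                for p in parents.get(node, ()):
                    c = colour.get(p, WHITE)
                    if c == GREY:
                        raise PedigreeValidationError(
                            f"pedigree cycle involving {p!r}"
                        )
                    if c == WHITE:
                        stack.append((p, False))

    @property
    def individual_ids(self) -> list[str]:
        return [r[0] for r in self.records]

    def parents_of(self, individual: str) -> tuple[str, str]:
        for ind, sire, dam in self.records:
            if ind == individual:
                return sire, dam
        raise KeyError(individual)

    def topological_order(self) -> list[str]:
        """All ids (parents included), parents before offspring."""
        recorded = {r[0]: (r[1], r[2]) for r in self.records}
        order: list[str] = []
        seen: set[str] = set()

        def visit(node: str) -> None:
            if node in seen or node == _UNKNOWN_PARENT:
                return
            seen.add(node)
            sire, dam = recorded.get(node, (_UNKNOWN_PARENT, _UNKNOWN_PARENT))
            visit(sire)
            visit(dam)
            order.append(node)

        for ind, sire, dam in self.records:
            visit(sire)
            visit(dam)
            visit(ind)
        return order


@dataclass
class PopulationSpec:
    """Family structure of one simulated population.

    ``half_sib_links`` are pairs of indices into ``family_sizes``; the
    two families share a sire.  Singletons get unique parents.
    """

    name: str
    n_singletons: int = 0
    family_sizes: list[int] = field(default_factory=list)
    half_sib_links: list[tuple[int, int]] = field(default_factory=list)

    def validate(self) -> None:
        if self.n_singletons < 0:
            raise ValueError(f"{self.name}: n_singletons < 0")
        if any(s < 1 for s in self.family_sizes):
            raise ValueError(f"{self.name}: family sizes must be >= 1")
        n_fam = len(self.family_sizes)
        for a, b in self.half_sib_links:
            if a == b or not (0 <= a < n_fam and 0 <= b < n_fam):
                raise ValueError(
                    f"{self.name}: half-sib link ({a},{b}) references "
                    f"invalid families (have {n_fam})"
                )


@dataclass
class SimConfig:
    """All knobs of the synthetic-data generator (see ``synthetic_data``)."""

    populations: list[PopulationSpec]
    n_snps: int = 3000
    maf_low: float = 0.02
    maf_high: float = 0.5
    fst_target: float = 0.01
    missing_rate: float = 0.05
    missing_profile: str = "bimodal"
    genotyping_error_rate: float = 0.001
    fragment_pair_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for rate, name in (
            (self.missing_rate, "missing_rate"),
            (self.genotyping_error_rate, "genotyping_error_rate"),
            (self.fragment_pair_fraction, "fragment_pair_fraction"),
        ):
            if not 0 <= rate <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        if not 0 <= self.fst_target < 1:
            raise ValueError("fst_target must be in [0, 1)")
        if not 0 <= self.maf_low <= self.maf_high <= 0.5:
            raise ValueError("require 0 <= maf_low <= maf_high <= 0.5")
        for spec in self.populations:
            spec.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text())
        pops = [
            PopulationSpec(
                name=p["name"],
                n_singletons=p.get("n_singletons", 0),
                family_sizes=list(p.get("family_sizes", [])),
                half_sib_links=[tuple(l) for l in p.get("half_sib_links", [])],
            )
            for p in raw.pop("populations")
        ]
        return cls(populations=pops, **raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "populations": [
                {
                    "name": p.name,
                    "n_singletons": p.n_singletons,
                    "family_sizes": list(p.family_sizes),
                    "half_sib_links": [list(l) for l in p.half_sib_links],
                }
                for p in self.populations
            ],
            "n_snps": self.n_snps,
            "maf_low": self.maf_low,
            "maf_high": self.maf_high,
            "fst_target": self.fst_target,
            "missing_rate": self.missing_rate,
            "missing_profile": self.missing_profile,
            "genotyping_error_rate": self.genotyping_error_rate,
            "fragment_pair_fraction": self.fragment_pair_fraction,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


# ---------------------------------------------------------------------------
# Genotype CSV I/O
#
# Schema: row 1 header  ``id,pop,hatchery,<snp_id>...``
#         row 2         ``#fragment,,,<fragment_id>...``
#         one row per individual thereafter; missing call written "NA".
# ---------------------------------------------------------------------------

_META_COLS = 3


def write_genotypes(g: GenotypeMatrix, path: str | Path) -> None:
    """Write the two-header genotype CSV (lossless round trip)."""
    path = Path(path)

    def line(cells: list[str]) -> str:
        return ",".join(cells) + "\n"

    with path.open("w") as fh:
        fh.write(line(["id", "pop", "hatchery", *g.snp_ids]))
        fh.write(line(["#fragment", "", "", *g.fragment_ids]))
        for i, ind in enumerate(g.individual_ids):
            row = ["NA" if c == MISSING else str(int(c)) for c in g.calls[i]]
            fh.write(line([ind, g.populations[i], g.hatcheries[i], *row]))


def _read_genotypes_csv(path: Path) -> GenotypeMatrix:
    with path.open() as fh:
        lines = fh.read().splitlines()
    if len(lines) < 2:
        raise GenotypeParseError(f"{path}: need header and #fragment rows")
    header = lines[0].split(",")
    if header[:_META_COLS] != ["id", "pop", "hatchery"]:
        raise GenotypeParseError(
            f"{path}:1: header must start 'id,pop,hatchery', got {header[:3]}"
        )
    snp_ids = header[_META_COLS:]
    frag_row = lines[1].split(",")
    if frag_row[0] != "#fragment":
        raise GenotypeParseError(f"{path}:2: expected '#fragment' row")
    fragment_ids = frag_row[_META_COLS:]
    if len(fragment_ids) != len(snp_ids):
        raise GenotypeParseError(f"{path}:2: fragment count != SNP count")

    individual_ids: list[str] = []
    populations: list[str] = []
    hatcheries: list[str] = []
    rows: list[list[int]] = []
    for lineno, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        cells = line.split(",")
        if len(cells) != _META_COLS + len(snp_ids):
            raise GenotypeParseError(
                f"{path}:{lineno}: expected {_META_COLS + len(snp_ids)} "
                f"columns, got {len(cells)}"
            )
        individual_ids.append(cells[0])
        populations.append(cells[1])
        hatcheries.append(cells[2])
        row: list[int] = []
        for col, cell in enumerate(cells[_META_COLS:], start=_META_COLS + 1):
            if cell == "NA":
                row.append(MISSING)
            elif cell in ("0", "1", "2"):
                row.append(int(cell))
            else:
                raise GenotypeParseError(
                    f"{path}:{lineno}:{col}: invalid call {cell!r} "
                    "(expected 0/1/2/NA)"
                )
        rows.append(row)
    calls = (
        np.array(rows, dtype=np.int16)
        if rows
        else np.empty((0, len(snp_ids)), dtype=np.int16)
    )
    return GenotypeMatrix(
        individual_ids=individual_ids,
        snp_ids=snp_ids,
        fragment_ids=fragment_ids,
        populations=populations,
        hatcheries=hatcheries,
        calls=calls,
    )


def _read_genotypes_vcf(path: Path) -> GenotypeMatrix:
    # biallelic SNPs only; GT -> count of alternate alleles; half calls
    # and multiallelic records are rejected rather than guessed at.
    try:
        from cyvcf2 import VCF
    except ImportError as e:  # pragma: no cover
        raise ImportError("VCF ingest requires the optional cyvcf2 dependency") from e

    vcf = VCF(str(path))
    individual_ids = list(vcf.samples)
    snp_ids: list[str] = []
    fragment_ids: list[str] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise GenotypeParseError(
                f"{path}: multiallelic record at {rec.CHROM}:{rec.POS}"
            )
        gts = rec.genotype.array()  # (n_samples, ploidy+1); last col = phase
        alleles = gts[:, :2]
        col = np.empty(len(individual_ids), dtype=np.int16)
        for i, pair in enumerate(alleles):
            if (pair < 0).all():
                col[i] = MISSING
            elif (pair < 0).any():
                raise GenotypeParseError(
                    f"{path}: half call for sample {individual_ids[i]} "
                    f"at {rec.CHROM}:{rec.POS}"
                )
            else:
                col[i] = int((pair == 1).sum())
        snp_ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        fragment_ids.append(rec.CHROM)
        columns.append(col)
    calls = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(individual_ids), 0), dtype=np.int16)
    )
    return GenotypeMatrix(
        individual_ids=individual_ids,
        snp_ids=snp_ids,
        fragment_ids=fragment_ids,
        populations=[""] * len(individual_ids),
        calls=calls,
    )


def read_genotypes(path: str | Path, format: str = "csv") -> GenotypeMatrix:
    """Read a genotype matrix from the documented CSV schema or a VCF.

    The counted allele is the alternate allele as given in the input;
    no re-polarisation happens on ingest (MAF is recomputed downstream).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        g = _read_genotypes_csv(path)
    elif format == "vcf":
        g = _read_genotypes_vcf(path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    log.info(
        "read %d individuals, %d SNPs on %d fragments, missing rate %.4f from %s",
        g.n_individuals,
        g.n_snps,
        len(set(g.fragment_ids)),
        g.missing_rate(),
        path,
    )
    return g


# ---------------------------------------------------------------------------
# Pedigree CSV I/O (three columns: id, sire, dam; unknown parent = "0")
# ---------------------------------------------------------------------------


def write_pedigree(p: Pedigree, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("id,sire,dam\n")
        for ind, sire, dam in p.records:
            fh.write(f"{ind},{sire},{dam}\n")


def read_pedigree(path: str | Path) -> Pedigree:
    path = Path(path)
    records: list[tuple[str, str, str]] = []
    with path.open() as fh:
        header = fh.readline().strip().split(",")
        if header != ["id", "sire", "dam"]:
            raise GenotypeParseError(f"{path}:1: expected header 'id,sire,dam'")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.strip().split(",")
            if len(cells) != 3:
                raise GenotypeParseError(f"{path}:{lineno}: expected 3 columns")
            records.append((cells[0], cells[1], cells[2]))
    return Pedigree(records=records)


def write_run_report(report: dict, path: str | Path) -> None:
    """Persist a machine-readable run report as JSON."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
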