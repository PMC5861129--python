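"""Domain types and tabular I/O for the monoterpene strain-engineering pipeline.

The pipeline operates on six kinds of flat tables, all plain CSV (tab-separated
accepted on read): a promoter catalog (rank-ordered names), strain designs
(promoter assigned to each of the four pathway genes), relative protein
abundances from targeted proteomics, monoterpene titers from GC-MS (mg/L),
sugar/ethanol profiles from HPLC (g/L), and commercial-beer target
concentrations.  Every reader validates its records against the type
invariants below and reports offending rows with line numbers rather than
silently coercing.
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

__all__ = [
    "GENES",
    "GENE_ALIASES",
    "SchemaError",
    "TableParseError",
    "UnknownPromoterError",
    "PromoterCatalog",
    "StrainDesign",
    "ProteinProfile",
    "MonoterpeneMeasurement",
    "SugarProfile",
    "TargetBeer",
    "RunConfig",
    "StrainDataset",
    "promoter_strength",
    "canonical_gene",
    "read_catalog",
    "read_designs",
    "read_proteins",
    "read_titers",
    "read_sugars",
    "read_targets",
    "write_table",
    "write_catalog",
    "default_catalog",
]

#: Canonical identifiers for the four modulated pathway genes: truncated
#: HMG-CoA reductase, the low-processivity FPP-synthase mutant, linalool
#: synthase and geraniol synthase.
GENES: tuple[str, ...] = ("tHMGR", "FPPS_star", "LIS", "GES")

#: Fixed alias map applied on read; keys are lower-cased before lookup.
GENE_ALIASES: dict[str, str] = {
    "thmgr": "tHMGR",
    "fpps_star": "FPPS_star",
    "fpps*": "FPPS_star",
    "fppsstar": "FPPS_star",
    "erg20_star": "FPPS_star",
    "erg20*": "FPPS_star",
    "lis": "LIS",
    "t67-mclis": "LIS",
    "t67_mclis": "LIS",
    "mclis": "LIS",
    "ges": "GES",
    "obges": "GES",
}


class SchemaError(ValueError):
    """A table is missing required columns or a record violates an invariant."""


class TableParseError(ValueError):
    """A cell could not be parsed; the message carries file and line number."""


class UnknownPromoterError(KeyError):
    """A promoter name was looked up that is not in the catalog."""

    def __init__(self, name: str) -> None:
        super().__init__(name)
        self.name = name

    def __str__(self) -> str:  # KeyError quotes its arg; keep a readable message
        return f"unknown promoter {self.name!r}: not in catalog"


def canonical_gene(name: str) -> str:
    """Normalize a gene label (e.g. ``ObGES``, ``t67-McLIS``) to its canonical id."""
    key = name.strip().lower()
    try:
        return GENE_ALIASES[key]
    except KeyError:
        raise SchemaError(
            f"unknown gene identifier {name!r}; "
            f"expected one of {sorted(set(GENE_ALIASES.values()))}"
        ) from None


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PromoterCatalog:
    """Rank-ordered promoter set with rank-derived strengths in [0, 1].

    Promoters are characterized only by their previously reported rank order,
    so strength is the rank expressed as a fraction of the maximum rank: the
    weakest promoter maps to 0 and the strongest to 1, evenly spaced between.
    """

    entries: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if len(self.entries) < 2:
            raise SchemaError("promoter catalog needs at least 2 entries")
        names = [n for n, _ in self.entries]
        ranks = sorted(r for _, r in self.entries)
        if len(set(names)) != len(names):
            raise SchemaError("duplicate promoter names in catalog")
        if ranks != list(range(len(ranks))):
            raise SchemaError(
                f"promoter ranks must be unique and contiguous from 0, got {ranks}"
            )

    @property
    def names(self) -> tuple[str, ...]:
        """Promoter names in ascending rank (weakest first)."""
        return tuple(n for n, _ in sorted(self.entries, key=lambda e: e[1]))

    def rank(self, name: str) -> int:
        for n, r in self.entries:
            if n == name:
                return r
        raise UnknownPromoterError(name)

    def strength(self, name: str) -> float:
        return promoter_strength(self, name)

    def __contains__(self, name: object) -> bool:
        return any(n == name for n, _ in self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def promoter_strength(catalog: PromoterCatalog, name: str) -> float:
    """Rank-derived promoter strength: rank / max_rank, on [0, 1].

    Raises :class:`UnknownPromoterError` for a name outside the catalog.
    """
    rank = catalog.rank(name)
    max_rank = len(catalog) - 1
    return rank / max_rank


@dataclass(frozen=True)
class StrainDesign:
    """A promoter assignment for each of the four modulated pathway genes."""

    strain_id: str
    promoter_of: Mapping[str, str]

    def __post_init__(self) -> None:
        got = set(self.promoter_of)
        if got != set(GENES):
            raise SchemaError(
                f"design {self.strain_id!r}: genes {sorted(got)} != required {sorted(GENES)}"
            )

    def validate_against(self, catalog: PromoterCatalog) -> None:
        for prom in self.promoter_of.values():
            if prom not in catalog:
                raise UnknownPromoterError(prom)


def _check_finite_nonneg(label: str, **values: float) -> None:
    for key, v in values.items():
        if not math.isfinite(v) or v < 0:
            raise SchemaError(f"{label}: {key}={v!r} must be finite and >= 0")


@dataclass(frozen=True)
class ProteinProfile:
    """Relative (unitless) protein abundance per pathway gene for one strain."""

    strain_id: str
    abundance: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.abundance) != set(GENES):
            raise SchemaError(
                f"profile {self.strain_id!r}: genes {sorted(self.abundance)} != {sorted(GENES)}"
            )
        _check_finite_nonneg(f"profile {self.strain_id!r}", **dict(self.abundance))


@dataclass(frozen=True)
class MonoterpeneMeasurement:
    """Linalool and geraniol titers (mg/L) for one replicate fermentation."""

    strain_id: str
    replicate: int
    linalool: float
    geraniol: float

    def __post_init__(self) -> None:
        _check_finite_nonneg(
            f"titer {self.strain_id!r}/{self.replicate}",
            linalool=self.linalool,
            geraniol=self.geraniol,
        )


@dataclass(frozen=True)
class SugarProfile:
    """End-of-fermentation sugar and ethanol concentrations (g/L)."""

    strain_id: str
    maltotriose: float
    maltose: float
    glucose: float
    ethanol: float

    def __post_init__(self) -> None:
        _check_finite_nonneg(
            f"sugars {self.strain_id!r}",
            maltotriose=self.maltotriose,
            maltose=self.maltose,
            glucose=self.glucose,
            ethanol=self.ethanol,
        )

    @property
    def total_fermentable(self) -> float:
        return self.maltotriose + self.maltose + self.glucose


@dataclass(frozen=True)
class TargetBeer:
    """Target monoterpene concentrations (mg/L) of a commercial reference beer."""

    name: str
    linalool: float
    geraniol: float

    def __post_init__(self) -> None:
        for key in ("linalool", "geraniol"):
            v = getattr(self, key)
            if not math.isfinite(v) or v <= 0:
                raise SchemaError(
                    f"target {self.name!r}: {key}={v!r} must be finite and > 0 "
                    "(log10 is taken)"
                )


@dataclass
class RunConfig:
    """Run configuration: seed, noise levels, model choice, optimizer settings, paths.

    Loaded from / saved to JSON.  ``seed`` must be set whenever any stochastic
    stage (simulation, fitting, policy evaluation) is enabled.
    """

    seed: int | None = None
    protein_cv: float = 0.2
    titer_cv: float = 0.15
    od_sd: float = 0.01
    model: str = "kinetic"  # kinetic | loglinear | smooth
    replicates: int = 3
    n_strains: int = 18
    de_popsize: int = 15
    de_maxiter: int = 300
    kernel_scale: float = 1.0
    log_floor_titer: float = 0.01  # mg/L
    log_floor_sugar: float = 0.01  # g/L
    strong_threshold: float = 0.67
    burden_slope: float = 0.2
    paths: dict[str, str] = field(default_factory=dict)

    def require_seed(self) -> int:
        if self.seed is None:
            raise SchemaError("config: seed is required when stochastic stages are enabled")
        return int(self.seed)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"config: unknown keys {sorted(unknown)}")
        return cls(**raw)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


@dataclass
class StrainDataset:
    """Per-strain measurements assembled for modeling.

    Holds the protein profiles and titer replicates (and optionally the
    designs, sugar profiles and unfermented wort) for one iteration of
    strains.  Strain order follows ``profiles``.
    """

    profiles: list[ProteinProfile]
    titers: list[MonoterpeneMeasurement]
    designs: list[StrainDesign] | None = None
    sugars: list[SugarProfile] | None = None
    wort: SugarProfile | None = None

    def __post_init__(self) -> None:
        ids = {p.strain_id for p in self.profiles}
        missing = {t.strain_id for t in self.titers} - ids
        if missing:
            raise SchemaError(f"titers reference unknown strains {sorted(missing)}")

    @property
    def strain_ids(self) -> list[str]:
        return [p.strain_id for p in self.profiles]

    def abundance_matrix(self) -> "tuple[list[str], list[list[float]]]":
        """(strain_ids, rows) with columns in canonical GENES order."""
        ids = self.strain_ids
        rows = [[p.abundance[g] for g in GENES] for p in self.profiles]
        return ids, rows

    def mean_titers(self) -> dict[str, tuple[float, float]]:
        """Replicate-averaged (linalool, geraniol) per strain."""
        acc: dict[str, list[tuple[float, float]]] = {}
        for t in self.titers:
            acc.setdefault(t.strain_id, []).append((t.linalool, t.geraniol))
        out = {}
        for sid in self.strain_ids:
            if sid not in acc:
                raise SchemaError(f"strain {sid!r} has a profile but no titer measurements")
            pairs = acc[sid]
            out[sid] = (
                sum(p[0] for p in pairs) / len(pairs),
                sum(p[1] for p in pairs) / len(pairs),
            )
        return out

    def drop_strain(self, strain_id: str) -> "StrainDataset":
        """Copy of the dataset without one strain (for leave-one-out folds)."""
        if strain_id not in set(self.strain_ids):
            raise KeyError(strain_id)
        return StrainDataset(
            profiles=[p for p in self.profiles if p.strain_id != strain_id],
            titers=[t for t in self.titers if t.strain_id != strain_id],
            designs=(
                None
                if self.designs is None
                else [d for d in self.designs if d.strain_id != strain_id]
            ),
            sugars=(
                None
                if self.sugars is None
                else [s for s in self.sugars if s.strain_id != strain_id]
            ),
            wort=self.wort,
        )

    def profile_of(self, strain_id: str) -> ProteinProfile:
        for p in self.profiles:
            if p.strain_id == strain_id:
                return p
        raise KeyError(strain_id)

    def __len__(self) -> int:
        return len(self.profiles)


def default_catalog() -> PromoterCatalog:
    """A representative 8-promoter yeast-toolkit-style catalog, weakest to strongest.

    The original study's exact promoter assignments are not distributed with
    this package; this stand-in preserves the structure the analysis needs (a
    rank order from a weak pRNR2-like promoter to a strong pTDH3-like one).
    """
    names = ["pRNR2", "pPOP6", "pRPL18B", "pRNR1", "pSAC6", "pTEF1", "pCCW12", "pTDH3"]
    return PromoterCatalog(tuple((n, i) for i, n in enumerate(names)))


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

# Deterministic column order per record type, used by write_table.
_COLUMNS: dict[type, tuple[str, ...]] = {
    MonoterpeneMeasurement: ("strain_id", "replicate", "linalool", "geraniol"),
    SugarProfile: ("strain_id", "maltotriose", "maltose", "glucose", "ethanol"),
    TargetBeer: ("name", "linalool", "geraniol"),
}

_FLOAT_FMT = "%.10g"


def _sniff_rows(path: str | Path) -> tuple[list[str], list[list[str]]]:
    """Read a delimited text table; comma by default, tab accepted by sniffing."""
    text = Path(path).read_text(encoding="utf-8")
    if not text.strip():
        raise SchemaError(f"{path}: empty table")
    first_line = text.splitlines()[0]
    delim = "\t" if first_line.count("\t") > first_line.count(",") else ","
    rows = list(csv.reader(io.StringIO(text), delimiter=delim))
    header = [h.strip() for h in rows[0]]
    body = [r for r in rows[1:] if any(cell.strip() for cell in r)]
    return header, body


def _column_index(path, header: list[str], required: Sequence[str]) -> dict[str, int]:
    lower = [h.lower() for h in header]
    idx: dict[str, int] = {}
    for col in required:
        try:
            idx[col] = lower.index(col.lower())
        except ValueError:
            raise SchemaError(
                f"{path}: missing required column {col!r} (found {header})"
            ) from None
    return idx


def _parse_float(path, lineno: int, col: str, raw: str) -> float:
    try:
        return float(raw)
    except ValueError:
        raise TableParseError(
            f"{path}:{lineno}: column {col!r}: cannot parse {raw!r} as a number"
        ) from None


def _parse_int(path, lineno: int, col: str, raw: str) -> int:
    try:
        return int(raw)
    except ValueError:
        raise TableParseError(
            f"{path}:{lineno}: column {col!r}: cannot parse {raw!r} as an integer"
        ) from None


def read_catalog(path: str | Path) -> PromoterCatalog:
    header, body = _sniff_rows(path)
    idx = _column_index(path, header, ["promoter", "rank"])
    entries = []
    for i, row in enumerate(body, start=2):
        name = row[idx["promoter"]].strip()
        rank = _parse_int(path, i, "rank", row[idx["rank"]].strip())
        entries.append((name, rank))
    return PromoterCatalog(tuple(entries))


def _gene_columns(path, header: list[str]) -> dict[str, int]:
    """Map canonical gene -> column index, accepting aliases in the header."""
    mapping: dict[str, int] = {}
    for j, h in enumerate(header):
        key = h.strip().lower()
        if key in GENE_ALIASES:
            mapping[GENE_ALIASES[key]] = j
    missing = set(GENES) - set(mapping)
    if missing:
        raise SchemaError(f"{path}: missing gene columns {sorted(missing)} (found {header})")
    return mapping


def read_designs(path: str | Path, catalog: PromoterCatalog | None = None) -> list[StrainDesign]:
    header, body = _sniff_rows(path)
    sid = _column_index(path, header, ["strain_id"])["strain_id"]
    genes = _gene_columns(path, header)
    designs = []
    for row in body:
        promoter_of = {g: row[j].strip() for g, j in genes.items()}
        d = StrainDesign(strain_id=row[sid].strip(), promoter_of=promoter_of)
        if catalog is not None:
            d.validate_against(catalog)
        designs.append(d)
    return designs


def read_proteins(path: str | Path) -> list[ProteinProfile]:
    header, body = _sniff_rows(path)
    sid = _column_index(path, header, ["strain_id"])["strain_id"]
    genes = _gene_columns(path, header)
    profiles = []
    for i, row in enumerate(body, start=2):
        abundance = {g: _parse_float(path, i, g, row[j].strip()) for g, j in genes.items()}
        profiles.append(ProteinProfile(strain_id=row[sid].strip(), abundance=abundance))
    return profiles


def read_titers(path: str | Path) -> list[MonoterpeneMeasurement]:
    header, body = _sniff_rows(path)
    idx = _column_index(path, header, _COLUMNS[MonoterpeneMeasurement])
    out = []
    for i, row in enumerate(body, start=2):
        out.append(
            MonoterpeneMeasurement(
                strain_id=row[idx["strain_id"]].strip(),
                replicate=_parse_int(path, i, "replicate", row[idx["replicate"]].strip()),
                linalool=_parse_float(path, i, "linalool", row[idx["linalool"]].strip()),
                geraniol=_parse_float(path, i, "geraniol", row[idx["geraniol"]].strip()),
            )
        )
    return out


def read_sugars(path: str | Path) -> list[SugarProfile]:
    header, body = _sniff_rows(path)
    idx = _column_index(path, header, _COLUMNS[SugarProfile])
    out = []
    for i, row in enumerate(body, start=2):
        out.append(
            SugarProfile(
                strain_id=row[idx["strain_id"]].strip(),
                **{
                    c: _parse_float(path, i, c, row[idx[c]].strip())
                    for c in ("maltotriose", "maltose", "glucose", "ethanol")
                },
            )
        )
    return out


def read_targets(path: str | Path) -> list[TargetBeer]:
    header, body = _sniff_rows(path)
    idx = _column_index(path, header, _COLUMNS[TargetBeer])
    return [
        TargetBeer(
            name=row[idx["name"]].strip(),
            linalool=_parse_float(path, i, "linalool", row[idx["linalool"]].strip()),
            geraniol=_parse_float(path, i, "geraniol", row[idx["geraniol"]].strip()),
        )
        for i, row in enumerate(body, start=2)
    ]


def _record_row(rec) -> tuple[list[str], list[str]]:
    """(columns, formatted values) for one record, deterministic order."""
    if isinstance(rec, StrainDesign):
        cols = ["strain_id", *GENES]
        vals = [rec.strain_id] + [rec.promoter_of[g] for g in GENES]
    elif isinstance(rec, ProteinProfile):
        cols = ["strain_id", *GENES]
        vals = [rec.strain_id] + [_FLOAT_FMT % rec.abundance[g] for g in GENES]
    else:
        cols = list(_COLUMNS[type(rec)])
        vals = []
        for c in cols:
            v = getattr(rec, c)
            vals.append(_FLOAT_FMT % v if isinstance(v, float) else str(v))
    return cols, vals


def write_table(records: Sequence, path: str | Path) -> None:
    """Write homogeneous records as CSV with fixed column order and formatting.

    Two runs over the same records produce byte-identical files.  An empty
    record list is an error and no file is created.
    """
    records = list(records)
    if not records:
        raise ValueError("write_table: empty record list")
    first_type = type(records[0])
    if first_type not in (StrainDesign, ProteinProfile, *_COLUMNS):
        raise TypeError(f"write_table: unsupported record type {first_type.__name__}")
    if any(type(r) is not first_type for r in records):
        raise TypeError("write_table: records must be homogeneous")
    cols, _ = _record_row(records[0])
    lines = [",".join(cols)]
    for rec in records:
        _, vals = _record_row(rec)
        lines.append(",".join(vals))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_catalog(catalog: PromoterCatalog, path: str | Path) -> None:
    lines = ["promoter,rank"]
    for name, rank in sorted(catalog.entries, key=lambda e: e[1]):
        lines.append(f"{name},{rank}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
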