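"""Data model and I/O for seabird regurgitate samples and the prey-taxon catalog.

The sampling unit is a regurgitate: the stomach content a handled bird
spontaneously ejects.  Each sample holds one :class:`PreyItem` per prey taxon
found in it, with the taxon's wet mass in grams and any otolith measurements.
Early-era samples carry only presence/absence information (``mass_based =
False``) and can enter occurrence-based metrics but not mass-based ones.

Taxa are classified by biogeographic origin (Arctic, Atlantic, mesopelagic or
intermediate) through a :class:`TaxonCatalog`; taxa missing from the catalog
are treated as unidentified and excluded from origin aggregates.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import pandas as pd

ORIGINS = ("arctic", "atlantic", "mesopelagic", "intermediate", "unidentified")
GROUPS = ("fish", "crustacea", "other")
COLONIES = ("Krykkjefjellet", "Irgensfjellet", "Observasjonsholmen", "unknown")
STAGES = ("incubation", "chick_rearing", "unknown")
BIRDS = ("adult", "chick", "unknown")
SEXES = ("male", "female", "unknown")

#: CSV column order of the long sample schema.
SAMPLE_COLUMNS = [
    "sample_id", "date", "year", "colony", "stage", "bird", "sex",
    "taxon", "wet_mass_g", "count", "otolith_lengths_mm", "presence_only",
]


@dataclass(frozen=True)
class PreyItem:
    """One prey taxon inside one regurgitate."""

    taxon: str
    wet_mass: float | None = None  # grams; None = presence-only record
    otolith_lengths: tuple[float, ...] = ()
    count: int | None = None

    def __post_init__(self) -> None:
        if self.wet_mass is not None and self.wet_mass < 0:
            raise ValueError(
                f"negative wet mass {self.wet_mass} g for taxon {self.taxon!r}"
            )
        if self.count is not None and self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")


@dataclass(frozen=True)
class DietSample:
    """A single regurgitate with its collection metadata."""

    sample_id: str
    year: int
    date: dt.date | None = None
    colony: str = "unknown"
    stage: str = "unknown"
    bird: str = "unknown"
    sex: str = "unknown"
    items: tuple[PreyItem, ...] = ()
    mass_based: bool = True

    def __post_init__(self) -> None:
        if not self.mass_based and any(i.wet_mass is not None for i in self.items):
            raise ValueError(
                f"presence-only sample {self.sample_id!r} carries wet masses"
            )

    @property
    def total_mass(self) -> float:
        """Total wet mass of the sample in grams (mass-based samples only)."""
        if not self.mass_based:
            raise ValueError(
                f"sample {self.sample_id!r} is presence-only; no masses recorded"
            )
        return sum(i.wet_mass or 0.0 for i in self.items)

    def taxa(self) -> set[str]:
        return {i.taxon for i in self.items}


@dataclass(frozen=True)
class CatalogEntry:
    common_name: str
    group: str
    origin: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}")


class TaxonCatalog:
    """Maps prey taxa to common names, main groups and origin classes.

    Origin aggregates (e.g. "mass of Arctic prey in a sample") use only taxa
    resolvable here; anything else counts as unidentified and is left out of
    origin-level statistics.
    """

    def __init__(self, entries: dict[str, CatalogEntry]):
        self.entries = dict(entries)

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def origin_of(self, taxon: str) -> str:
        entry = self.entries.get(taxon)
        return entry.origin if entry is not None else "unidentified"

    def taxa_of_origin(self, origin: str) -> list[str]:
        if origin not in ORIGINS:
            raise ValueError(f"unknown origin {origin!r}")
        return [t for t, e in self.entries.items() if e.origin == origin]

    @classmethod
    def from_csv(cls, path) -> "TaxonCatalog":
        df = pd.read_csv(path, comment="#")
        entries = {
            str(r.taxon): CatalogEntry(str(r.common_name), str(r.group), str(r.origin))
            for r in df.itertuples()
        }
        return cls(entries)

    def to_csv(self, path) -> None:
        rows = [
            {"taxon": t, "common_name": e.common_name, "group": e.group,
             "origin": e.origin}
            for t, e in self.entries.items()
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def default_catalog() -> TaxonCatalog:
    """Catalog of the prey taxa recorded in Kongsfjorden kittiwake regurgitates.

    Origin membership: Arctic = polar cod and Themisto libellula; Atlantic =
    capelin, herring, Atlantic cod, haddock; mesopelagic = glacier lanternfish,
    white barracudina, Pasiphaea tarda; all remaining identified taxa are
    intermediate.  Users with different classifications supply their own
    catalog CSV.
    """
    def e(common, group, origin):
        return CatalogEntry(common, group, origin)

    return TaxonCatalog({
        "polar cod": e("Boreogadus saida", "fish", "arctic"),
        "capelin": e("Mallotus villosus", "fish", "atlantic"),
        "Atlantic herring": e("Clupea harengus", "fish", "atlantic"),
        "Atlantic cod": e("Gadus morhua", "fish", "atlantic"),
        "haddock": e("Melanogrammus aeglefinus", "fish", "atlantic"),
        "glacier lanternfish": e("Benthosema glaciale", "fish", "mesopelagic"),
        "white barracudina": e("Arctozenus risso", "fish", "mesopelagic"),
        "daubed shanny": e("Leptoclinus maculatus", "fish", "intermediate"),
        "snake blenny": e("Lumpenus lampretaeformis", "fish", "intermediate"),
        "rockfish": e("Sebastes spp.", "fish", "intermediate"),
        "shorthorn sculpin": e("Myoxocephalus scorpius", "fish", "intermediate"),
        "threespot eelpout": e("Lycodes rossi", "fish", "intermediate"),
        "Thysanoessa inermis": e("krill", "crustacea", "intermediate"),
        "Thysanoessa longicaudata": e("krill", "crustacea", "intermediate"),
        "Themisto libellula": e("amphipod", "crustacea", "arctic"),
        "Themisto abyssorum": e("amphipod", "crustacea", "intermediate"),
        "northern prawn": e("Pandalus borealis", "crustacea", "intermediate"),
        "Pasiphaea tarda": e("crimson pasiphaeid", "crustacea", "mesopelagic"),
        "Nereis spp.": e("polychaete", "other", "intermediate"),
        "Limacina helicina": e("pteropod", "other", "intermediate"),
        "Parasagitta elegans": e("chaetognath", "other", "intermediate"),
        "cephalopods": e("cephalopods", "other", "intermediate"),
        "trawler waste": e("trawler waste", "other", "intermediate"),
    })


@dataclass
class LoadReport:
    n_rows: int = 0
    n_samples: int = 0
    n_flagged_taxa: int = 0
    flagged_taxa: set[str] = field(default_factory=set)


class SampleTable:
    """An ordered collection of diet samples spanning one or more years."""

    def __init__(self, samples: list[DietSample]):
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids: {dup[:5]}")
        self.samples = list(samples)
        self.load_report: LoadReport | None = None

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def years(self) -> list[int]:
        return sorted({s.year for s in self.samples})

    def for_year(self, year: int) -> "SampleTable":
        return SampleTable([s for s in self.samples if s.year == year])

    def mass_based(self) -> "SampleTable":
        return SampleTable([s for s in self.samples if s.mass_based])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            base = {
                "sample_id": s.sample_id,
                "date": s.date.isoformat() if s.date else "",
                "year": s.year,
                "colony": s.colony,
                "stage": s.stage,
                "bird": s.bird,
                "sex": s.sex,
                "presence_only": 0 if s.mass_based else 1,
            }
            if not s.items:
                rows.append({**base, "taxon": "", "wet_mass_g": "",
                             "count": "", "otolith_lengths_mm": ""})
            for item in s.items:
                rows.append({
                    **base,
                    "taxon": item.taxon,
                    "wet_mass_g": "" if item.wet_mass is None else item.wet_mass,
                    "count": "" if item.count is None else item.count,
                    "otolith_lengths_mm": ";".join(
                        f"{v:g}" for v in item.otolith_lengths),
                })
        return pd.DataFrame(rows, columns=SAMPLE_COLUMNS)


def read_samples(path, catalog: TaxonCatalog) -> SampleTable:
    """Read a long-format sample CSV into a :class:`SampleTable`.

    One row per (sample, taxon); rows sharing a sample_id are merged into one
    sample.  Rows whose taxon is not in the catalog are retained but flagged in
    the load report attached as ``table.load_report``.

    Raises
    ------
    ValueError
        On negative masses, or duplicate (sample_id, taxon) rows whose masses
        conflict.
    """
    df = pd.read_csv(path, comment="#", dtype={"sample_id": str, "taxon": str},
                     keep_default_na=False)
    report = LoadReport(n_rows=len(df))
    samples: list[DietSample] = []
    for sid, grp in df.groupby("sample_id", sort=False):
        meta = grp.iloc[0]
        presence_only = bool(int(meta.get("presence_only", 0) or 0))
        date = None
        if str(meta.get("date", "")).strip():
            date = dt.date.fromisoformat(str(meta["date"]))
        year = int(meta["year"]) if str(meta.get("year", "")).strip() else None
        if year is None:
            if date is None:
                raise ValueError(f"sample {sid!r}: no year and no date")
            year = date.year
        items: dict[str, PreyItem] = {}
        for r in grp.itertuples():
            taxon = str(r.taxon).strip()
            if not taxon:
                continue  # placeholder row for an empty regurgitate
            mass = None
            raw = str(getattr(r, "wet_mass_g", "")).strip()
            if raw and not presence_only:
                mass = float(raw)
                if mass < 0:
                    raise ValueError(
                        f"sample {sid!r}, taxon {taxon!r}: negative mass {mass}")
            count = None
            raw_count = str(getattr(r, "count", "")).strip()
            if raw_count:
                count = int(float(raw_count))
            oto = tuple(
                float(v) for v in
                str(getattr(r, "otolith_lengths_mm", "")).split(";") if v.strip()
            )
            item = PreyItem(taxon, mass, oto, count)
            if taxon in items:
                prev = items[taxon]
                if prev.wet_mass != item.wet_mass:
                    raise ValueError(
                        f"sample {sid!r}: conflicting masses for taxon {taxon!r}")
                item = replace(prev, otolith_lengths=prev.otolith_lengths
                               + item.otolith_lengths)
            items[taxon] = item
            if taxon not in catalog:
                report.n_flagged_taxa += 1
                report.flagged_taxa.add(taxon)
        samples.append(DietSample(
            sample_id=str(sid), year=year, date=date,
            colony=str(meta.get("colony", "unknown") or "unknown"),
            stage=str(meta.get("stage", "unknown") or "unknown"),
            bird=str(meta.get("bird", "unknown") or "unknown"),
            sex=str(meta.get("sex", "unknown") or "unknown"),
            items=tuple(items.values()),
            mass_based=not presence_only,
        ))
    table = SampleTable(samples)
    report.n_samples = table.n_samples
    table.load_report = report
    return table


def write_samples(table: SampleTable, path) -> None:
    table.to_dataframe().to_csv(path, index=False)


def origin_mass(sample: DietSample, origin: str, catalog: TaxonCatalog) -> float:
    """Summed wet mass (g) of a sample's items belonging to an origin class.

    Unidentified taxa never contribute to named origin classes.  Requires a
    mass-based sample.
    """
    if origin not in ORIGINS:
        raise ValueError(f"unknown origin {origin!r}")
    if not sample.mass_based:
        raise ValueError(
            f"sample {sample.sample_id!r} is presence-only; "
            "mass-based metrics unavailable")
    return sum(
        i.wet_mass or 0.0 for i in sample.items
        if catalog.origin_of(i.taxon) == origin
    )


def presence_matrix(table: SampleTable, level: str = "taxon",
                    catalog: TaxonCatalog | None = None) -> pd.DataFrame:
    """Year x category matrix of occurrence counts.

    Cell (y, c) is the number of samples from year y that contain category c
    (a taxon, or an origin class when ``level='origin'``).  Per-year sample
    counts are attached as ``df.attrs['n_samples']``; years without samples do
    not appear.  Presence-only samples count identically to mass-based ones.
    """
    if table.n_samples == 0:
        raise ValueError("empty sample table")
    if level == "origin" and catalog is None:
        raise ValueError("origin-level matrix requires a catalog")
    counts: dict[int, dict[str, int]] = {}
    margins: dict[int, int] = {}
    for s in table:
        margins[s.year] = margins.get(s.year, 0) + 1
        row = counts.setdefault(s.year, {})
        if level == "taxon":
            cats = s.taxa()
        else:
            cats = {catalog.origin_of(i.taxon) for i in s.items}
            cats.discard("unidentified")
        for c in cats:
            row[c] = row.get(c, 0) + 1
    df = pd.DataFrame.from_dict(counts, orient="index").fillna(0).astype(int)
    df = df.sort_index().reindex(sorted(df.columns), axis=1)
    df.index.name = "year"
    df.attrs["n_samples"] = pd.Series(margins).sort_index()
    return df


def occurrence_frequencies(table: SampleTable, level: str = "taxon",
                           catalog: TaxonCatalog | None = None) -> pd.DataFrame:
    """Year x category frequency-of-occurrence matrix in percent."""
    counts = presence_matrix(table, level=level, catalog=catalog)
    margins = counts.attrs["n_samples"]
    fo = 100.0 * counts.div(margins, axis=0)
    fo.attrs["n_samples"] = margins
    return fo
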