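"""Cancer gene panel: loading, validation and subsetting.

The panel scopes every downstream triage decision: inheritance mode decides
actionability of heterozygous hits, the haploinsufficiency verdict gates the
loss-of-function candidate route, and the secondary-findings flag defines the
high-penetrance subset analysed separately.

The panel is an *input*, not something this package derives: the file carries
the reviewed per-gene verdicts. A default 95-gene reconstruction (25 of them
flagged as ACMG secondary-findings cancer genes) ships with the package; it is
a documented approximation of the kind of curated list such a study uses, not
an authoritative clinical resource.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .vocab import INHERITANCE_MODES

_REQUIRED_COLUMNS = ("symbol", "inheritance", "haploinsufficient", "acmg_sf")
_HAPLO_VALUES = ("yes", "no", "unknown")


@dataclass(frozen=True)
class GenePanelEntry:
    """One panel gene with its reviewed triage-relevant attributes."""

    symbol: str
    inheritance: str  # AD | AR | XL
    haploinsufficient: str  # yes | no | unknown
    acmg_sf: bool
    cancer_types: tuple[str, ...] = ()
    transcript: str | None = None

    def __post_init__(self) -> None:
        if self.inheritance not in INHERITANCE_MODES:
            raise ConfigurationError(
                f"gene {self.symbol}: unknown inheritance {self.inheritance!r} "
                f"(expected one of {sorted(INHERITANCE_MODES)})"
            )
        if self.haploinsufficient not in _HAPLO_VALUES:
            raise ConfigurationError(
                f"gene {self.symbol}: unknown haploinsufficiency verdict "
                f"{self.haploinsufficient!r} (expected one of {_HAPLO_VALUES})"
            )


class GenePanel:
    """An ordered, symbol-unique collection of :class:`GenePanelEntry`."""

    def __init__(self, entries: list[GenePanelEntry]):
        if not entries:
            raise ConfigurationError("panel is empty")
        seen: set[str] = set()
        for e in entries:
            if e.symbol in seen:
                raise ConfigurationError(f"duplicate gene symbol in panel: {e.symbol}")
            seen.add(e.symbol)
        self.entries = list(entries)
        self._by_symbol = {e.symbol: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._by_symbol

    def __getitem__(self, symbol: str) -> GenePanelEntry:
        return self._by_symbol[symbol]

    def get(self, symbol: str) -> GenePanelEntry | None:
        return self._by_symbol.get(symbol)

    @property
    def symbols(self) -> list[str]:
        return [e.symbol for e in self.entries]


def _entry_from_mapping(row: dict, source: str) -> GenePanelEntry:
    for col in _REQUIRED_COLUMNS:
        if row.get(col) in (None, ""):
            raise ConfigurationError(
                f"{source}: missing required field {col!r} "
                f"for row {row.get('symbol') or row!r}"
            )
    acmg_raw = str(row["acmg_sf"]).strip().lower()
    if acmg_raw not in ("true", "false", "yes", "no", "1", "0"):
        raise ConfigurationError(
            f"{source}: gene {row['symbol']}: acmg_sf must be boolean-like, "
            f"got {row['acmg_sf']!r}"
        )
    cancers = row.get("cancer_types") or ""
    if isinstance(cancers, str):
        cancer_types = tuple(t.strip() for t in cancers.split(";") if t.strip())
    else:
        cancer_types = tuple(cancers)
    transcript = row.get("transcript") or None
    return GenePanelEntry(
        symbol=str(row["symbol"]).strip(),
        inheritance=str(row["inheritance"]).strip(),
        haploinsufficient=str(row["haploinsufficient"]).strip().lower(),
        acmg_sf=acmg_raw in ("true", "yes", "1"),
        cancer_types=cancer_types,
        transcript=transcript,
    )


def load_panel(path: str | Path) -> GenePanel:
    """Load and validate a gene panel from a TSV (or YAML) file.

    TSV columns: symbol, inheritance, haploinsufficient, acmg_sf,
    cancer_types (semicolon-separated), transcript. A YAML file with a
    top-level ``genes:`` list of mappings with the same keys is also accepted.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"panel file not found: {path}")
    if path.suffix.lower() in (".yaml", ".yml"):
        doc = yaml.safe_load(path.read_text())
        if not doc or "genes" not in doc or not doc["genes"]:
            raise ConfigurationError(f"{path}: no genes found")
        rows = doc["genes"]
    else:
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            if reader.fieldnames is None:
                raise ConfigurationError(f"{path}: empty panel file")
            missing = [c for c in _REQUIRED_COLUMNS if c not in reader.fieldnames]
            if missing:
                raise ConfigurationError(
                    f"{path}: missing required column(s): {', '.join(missing)}"
                )
            rows = list(reader)
        if not rows:
            raise ConfigurationError(f"{path}: no genes found")
    return GenePanel([_entry_from_mapping(r, str(path)) for r in rows])


def write_panel(panel: GenePanel, path: str | Path) -> None:
    """Serialize a panel back to TSV (inverse of :func:`load_panel`)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["symbol", "inheritance", "haploinsufficient", "acmg_sf", "cancer_types", "transcript"]
        )
        for e in panel:
            writer.writerow(
                [
                    e.symbol,
                    e.inheritance,
                    e.haploinsufficient,
                    "true" if e.acmg_sf else "false",
                    ";".join(e.cancer_types),
                    e.transcript or "",
                ]
            )


def subset_acmg_sf(panel: GenePanel) -> GenePanel:
    """Return the secondary-findings subset of the panel, order preserved."""
    flagged = [e for e in panel if e.acmg_sf]
    if not flagged:
        # An empty GenePanel is normally a configuration error, but an empty
        # subset is a legitimate query result; bypass the constructor check.
        empty = object.__new__(GenePanel)
        empty.entries = []
        empty._by_symbol = {}
        return empty
    return GenePanel(flagged)


def default_panel_path() -> Path:
    """Path of the bundled 95-gene default panel."""
    return Path(resources.files("fhconcord").joinpath("data/default_panel.tsv"))


def load_default_panel() -> GenePanel:
    return load_panel(default_panel_path())
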