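"""Ligand-receptor interaction databases.

Models named ligand-receptor interactions in which either side may be a
heteromeric complex (an ordered list of gene symbols).  Two on-disk dialects
are supported:

* the CellPhoneDB v4 flat-CSV layout (``interaction_input.csv``,
  ``complex_input.csv``, ``protein_input.csv``, ``gene_input.csv``), in which
  interaction partners are protein or complex identifiers that must be
  resolved to gene symbols, and
* a generic two-column delimited pairs table (one single-gene ligand and one
  single-gene receptor per row), the layout used by CellTalkDB exports.

Databases can be merged; two interactions are considered the same pair when
their sorted ligand components and sorted receptor components coincide.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

log = logging.getLogger(__name__)

_CPDB_FILES = {
    "interactions": "interaction_input.csv",
    "complexes": "complex_input.csv",
    "proteins": "protein_input.csv",
    "genes": "gene_input.csv",
}

SCHEMA = "linksig-lrdb-1"


@dataclass(frozen=True)
class GeneComplex:
    """A ligand or receptor unit: one gene, or a heteromeric complex."""

    name: str
    components: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.components) == 0:
            raise ValueError(f"complex {self.name!r} has no components")
        if len(set(self.components)) != len(self.components):
            raise ValueError(f"complex {self.name!r} has duplicate components")
        object.__setattr__(self, "components", tuple(self.components))

    @property
    def is_complex(self) -> bool:
        return len(self.components) > 1


@dataclass(frozen=True)
class LRInteraction:
    id: str
    ligand: GeneComplex
    receptor: GeneComplex
    source: str = ""

    @property
    def pair_key(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        """Identity of the pair across databases: sorted components per side."""
        return (
            tuple(sorted(self.ligand.components)),
            tuple(sorted(self.receptor.components)),
        )


@dataclass
class LRDatabase:
    """A collection of ligand-receptor interactions with unique ids."""

    interactions: list[LRInteraction] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [i.id for i in self.interactions]
        if len(set(ids)) != len(ids):
            raise ValueError("interaction ids are not unique")

    def __len__(self) -> int:
        return len(self.interactions)

    def __iter__(self):
        return iter(self.interactions)

    @property
    def gene_universe(self) -> frozenset[str]:
        genes: set[str] = set()
        for inter in self.interactions:
            genes.update(inter.ligand.components)
            genes.update(inter.receptor.components)
        return frozenset(genes)

    def ligand_complexes(self) -> dict[str, GeneComplex]:
        return {i.ligand.name: i.ligand for i in self.interactions}

    def receptor_complexes(self) -> dict[str, GeneComplex]:
        return {i.receptor.name: i.receptor for i in self.interactions}

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema": SCHEMA,
            "interactions": [
                {
                    "id": i.id,
                    "source": i.source,
                    "ligand": {"name": i.ligand.name, "components": list(i.ligand.components)},
                    "receptor": {
                        "name": i.receptor.name,
                        "components": list(i.receptor.components),
                    },
                }
                for i in self.interactions
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "LRDatabase":
        inters = [
            LRInteraction(
                id=rec["id"],
                source=rec.get("source", ""),
                ligand=GeneComplex(rec["ligand"]["name"], tuple(rec["ligand"]["components"])),
                receptor=GeneComplex(
                    rec["receptor"]["name"], tuple(rec["receptor"]["components"])
                ),
            )
            for rec in data["interactions"]
        ]
        return cls(inters)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "LRDatabase":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _normalize(symbol: str, mode: str | None) -> str:
    if mode is None:
        return symbol
    if mode == "upper":
        return symbol.upper()
    if mode == "title":
        return symbol.capitalize()
    raise ValueError(f"unknown case normalization {mode!r}")


def _read_csv(path: Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path.name}, line 1: malformed header, missing column(s) {missing}"
        )
    return df


def load_cellphonedb(dir_path: str | Path, normalize_case: str | None = None) -> LRDatabase:
    """Load a CellPhoneDB v4 flat-CSV directory into an :class:`LRDatabase`.

    ``partner_a`` is taken as the ligand side and ``partner_b`` as the
    receptor side.  Partners are resolved to gene symbols via the gene table;
    complexes are expanded via the complex table.  A protein mapping to
    multiple genes is expanded to all of them.  Interactions with a partner
    that resolves to no gene are dropped (the number dropped is logged).
    """
    dir_path = Path(dir_path)
    paths = {}
    for key, fname in _CPDB_FILES.items():
        p = dir_path / fname
        if not p.exists():
            raise FileNotFoundError(f"missing required CellPhoneDB file: {fname}")
        paths[key] = p

    genes = _read_csv(paths["genes"], ["gene_name", "uniprot"])
    complexes = _read_csv(paths["complexes"], ["complex_name"])
    _read_csv(paths["proteins"], ["uniprot"])  # presence/shape check only
    inter = _read_csv(paths["interactions"], ["partner_a", "partner_b"])

    uniprot_to_genes: dict[str, list[str]] = {}
    for _, row in genes.iterrows():
        uniprot_to_genes.setdefault(str(row["uniprot"]), []).append(str(row["gene_name"]))

    member_cols = [c for c in complexes.columns if c.startswith("uniprot_")]
    complex_members: dict[str, list[str]] = {}
    for _, row in complexes.iterrows():
        members = [str(row[c]) for c in member_cols if pd.notna(row[c]) and str(row[c])]
        complex_members[str(row["complex_name"])] = members

    def resolve(partner: str) -> GeneComplex | None:
        if partner in complex_members:
            uniprots = complex_members[partner]
        else:
            uniprots = [partner]
        symbols: list[str] = []
        for up in uniprots:
            for g in uniprot_to_genes.get(up, []):
                g = _normalize(g, normalize_case)
                if g not in symbols:
                    symbols.append(g)
        if not symbols:
            return None
        return GeneComplex(partner, tuple(symbols))

    interactions: list[LRInteraction] = []
    n_dropped = 0
    id_col = "id_cp_interaction" if "id_cp_interaction" in inter.columns else None
    for idx, row in inter.iterrows():
        lig = resolve(str(row["partner_a"]))
        rec = resolve(str(row["partner_b"]))
        if lig is None or rec is None:
            n_dropped += 1
            continue
        iid = str(row[id_col]) if id_col else f"CPI-{idx}"
        interactions.append(LRInteraction(id=iid, ligand=lig, receptor=rec, source="cellphonedb"))
    if n_dropped:
        log.info("load_cellphonedb: dropped %d unresolvable interaction(s)", n_dropped)
    return LRDatabase(interactions)


def load_pairs_table(
    path: str | Path,
    ligand_col: str = "ligand",
    receptor_col: str = "receptor",
    source: str = "pairs_table",
    normalize_case: str | None = None,
) -> LRDatabase:
    """Load a two-column ligand/receptor table (CSV or TSV by extension).

    Each row yields one single-gene-per-side interaction; duplicated
    (ligand, receptor) rows collapse to a single interaction.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    for col in (ligand_col, receptor_col):
        if col not in df.columns:
            raise ValueError(f"{path.name}: required column {col!r} not found")
    seen: set[tuple[str, str]] = set()
    interactions = []
    for _, row in df.iterrows():
        lig = _normalize(str(row[ligand_col]), normalize_case)
        rec = _normalize(str(row[receptor_col]), normalize_case)
        if (lig, rec) in seen:
            continue
        seen.add((lig, rec))
        interactions.append(
            LRInteraction(
                id=f"{lig}_{rec}",
                ligand=GeneComplex(lig, (lig,)),
                receptor=GeneComplex(rec, (rec,)),
                source=source,
            )
        )
    return LRDatabase(interactions)


def merge_databases(a: LRDatabase, b: LRDatabase) -> LRDatabase:
    """Union of two databases, collapsing interactions that share a pair key.

    When the same (sorted ligand components, sorted receptor components) pair
    appears in both inputs, the interaction (and id) from ``a`` is kept.
    """
    merged: dict[tuple, LRInteraction] = {}
    used_ids: set[str] = set()
    for inter in list(a.interactions) + list(b.interactions):
        key = inter.pair_key
        if key in merged:
            continue
        iid = inter.id
        # ids must stay unique in the merged database
        k = 1
        while iid in used_ids:
            iid = f"{inter.id}.{k}"
            k += 1
        if iid is not inter.id and iid != inter.id:
            inter = LRInteraction(iid, inter.ligand, inter.receptor, inter.source)
        used_ids.add(iid)
        merged[key] = inter
    return LRDatabase(list(merged.values()))
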