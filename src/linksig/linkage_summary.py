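"""The Linkage Summary: per-subject linkages plus subject metadata.

A :class:`LinkageSummary` pairs an ordered subject metadata table (each
subject annotated with categorical grouping variables) with one
:class:`~linksig.ccci.SubjectLinkages` per subject.  It is the input to the
differential cell signaling test, and the common format into which the
output of any binarizable cell-cell communication method can be adapted
(``from_interaction_scores``).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .ccci import SubjectLinkages

log = logging.getLogger(__name__)

SCHEMA = "linksig-summary-1"

LINKAGE_CLASSES = SubjectLinkages.LINKAGE_CLASSES


@dataclass
class LinkageSummary:
    subjects: list[str]
    meta: pd.DataFrame  # indexed by subject, categorical variables as columns
    linkages: dict[str, SubjectLinkages]

    def __post_init__(self) -> None:
        if len(set(self.subjects)) != len(self.subjects):
            raise ValueError("duplicate subject ids")
        for s in self.subjects:
            if s not in self.meta.index:
                raise ValueError(f"subject {s!r} missing from metadata")
            if s not in self.linkages:
                raise ValueError(f"subject {s!r} missing from linkages")
        self.meta = self.meta.loc[self.subjects]

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def variables(self) -> list[str]:
        return list(self.meta.columns)


def build_summary(
    entries: list[tuple[str, SubjectLinkages]], meta: pd.DataFrame
) -> LinkageSummary:
    """Collate (subject, SubjectLinkages) pairs with a subject metadata table.

    ``meta`` is indexed by subject id or carries a ``subject`` column.
    Subjects keep the order given in ``entries``.
    """
    if "subject" in meta.columns:
        meta = meta.set_index("subject")
    subjects = [s for s, _ in entries]
    if len(set(subjects)) != len(subjects):
        raise ValueError("duplicate subject ids in entries")
    missing = [s for s in subjects if s not in meta.index]
    if missing:
        raise ValueError(f"subject(s) missing from metadata: {missing}")
    return LinkageSummary(
        subjects=subjects, meta=meta.loc[subjects].copy(),
        linkages={s: l for s, l in entries},
    )


def count_linkage(
    s: LinkageSummary,
    linkage_class: str,
    linkage: tuple,
    group_var: str,
    subjects: list[str] | None = None,
) -> dict[str, tuple[int, int]]:
    """Per group level, (subjects with linkage, subjects without)."""
    if group_var not in s.meta.columns:
        raise ValueError(f"unknown grouping variable {group_var!r}")
    linkage = tuple(linkage)
    included = s.subjects if subjects is None else [x for x in s.subjects if x in set(subjects)]
    out: dict[str, tuple[int, int]] = {}
    for subj in included:
        group = s.meta.loc[subj, group_var]
        n_with, n_without = out.get(group, (0, 0))
        if linkage in s.linkages[subj].linkage_set(linkage_class):
            out[group] = (n_with + 1, n_without)
        else:
            out[group] = (n_with, n_without + 1)
    return out


def unique_linkages(s: LinkageSummary, linkage_class: str, cell_type: str) -> list[tuple]:
    """All unique linkages of a class whose recipient cell type matches,
    across all subjects, in deterministic lexicographic order."""
    seen: set[tuple] = set()
    for subj in s.subjects:
        for linkage in s.linkages[subj].linkage_set(linkage_class):
            if linkage[0] == cell_type:
                seen.add(linkage)
    return sorted(seen)


def from_interaction_scores(
    tables: dict[str, pd.DataFrame],
    meta: pd.DataFrame,
    threshold: float = 0.1,
) -> LinkageSummary:
    """Binarize external interaction-probability tables into a summary.

    Each per-subject table has columns ``source`` (sender cell type),
    ``target`` (recipient cell type), ``ligand``, ``receptor``, ``prob``.
    An intercellular linkage is active iff its probability is strictly
    greater than ``threshold``.  Intracellular sets are left empty (the
    external method provides none).
    """
    entries = []
    for subj, table in tables.items():
        required = {"source", "target", "ligand", "receptor", "prob"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"subject {subj!r}: table missing column(s) {sorted(missing)}")
        probs = table["prob"].to_numpy(dtype=float)
        if (probs < 0).any() or (probs > 1).any():
            raise ValueError(f"subject {subj!r}: probabilities outside [0, 1]")
        active = table[probs > threshold]
        cl_rec_lig = {
            (str(r.target), str(r.receptor), str(r.ligand), str(r.source))
            for r in active.itertuples()
        }
        linkages = SubjectLinkages(
            subject=str(subj),
            cell_types=set(map(str, table["source"])) | set(map(str, table["target"])),
            rec={(t, r) for t, r, _, _ in cl_rec_lig},
            incoming_lig={(t, l) for t, _, l, _ in cl_rec_lig},
            cl_rec_lig=cl_rec_lig,
        )
        entries.append((str(subj), linkages))
    return build_summary(entries, meta)


# ---------------------------------------------------------------------------
# serialization


def write_summary(s: LinkageSummary, path: str | Path) -> None:
    doc = {
        "schema": SCHEMA,
        "subjects": list(s.subjects),
        "meta": {subj: {k: str(v) for k, v in s.meta.loc[subj].items()} for subj in s.subjects},
        "linkages": {subj: s.linkages[subj].to_dict() for subj in s.subjects},
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_summary(path: str | Path) -> LinkageSummary:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"cannot parse linkage summary {path}: {exc}") from exc
    for key in ("subjects", "meta", "linkages"):
        if key not in doc:
            raise ValueError(f"linkage summary {path}: missing key $.{key}")
    extra = set(doc) - {"schema", "subjects", "meta", "linkages"}
    if extra:
        warnings.warn(f"linkage summary has unknown key(s), ignored: {sorted(extra)}")
    subjects = [str(x) for x in doc["subjects"]]
    meta = pd.DataFrame.from_dict(doc["meta"], orient="index")
    meta.index.name = "subject"
    linkages = {}
    for subj in subjects:
        if subj not in doc["linkages"]:
            raise ValueError(f"linkage summary {path}: missing key $.linkages.{subj}")
        linkages[subj] = SubjectLinkages.from_dict(doc["linkages"][subj])
    return LinkageSummary(subjects=subjects, meta=meta, linkages=linkages)
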