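"""MedDRA-like terminology hierarchy and projection of reactions onto primary HLTs.

MedDRA itself is licensed, so this module defines a small open TSV dialect
for the part of the hierarchy the pipeline needs: each Preferred Term (PT)
maps to exactly one primary High-Level Term (HLT), each HLT to one
High-Level Group Term (HLGT) and one primary System Organ Class (SOC), and
Standardized MedDRA Queries (SMQs) are sets of PTs with a ``narrow`` and a
``broad`` scope.  Licensees can export the real dictionary into the same
dialect; the test suite uses a synthetic one.

Dictionary TSV columns (tab-separated, UTF-8, header row):
    ``pt``, ``primary_hlt``, ``hlgt``, ``primary_soc``
    and optionally ``pt_name``, ``hlt_name``, ``hlgt_name`` for display.

SMQ TSV columns: ``smq_name``, ``scope`` (narrow|broad), ``pt``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

#: The six non-specific System Organ Classes excluded from event projection.
DEFAULT_EXCLUDED_SOCS: frozenset[str] = frozenset(
    {
        "Injury, poisoning and procedural complications",
        "Social circumstances",
        "Product issues",
        "Surgical and medical procedures",
        "Investigations",
        "General disorders and administration site conditions",
    }
)


class HierarchyIntegrityError(ValueError):
    """Raised when a dictionary file violates a hierarchy invariant."""


@dataclass
class SOCExclusionList:
    """Set of SOC names whose HLTs are dropped during projection."""

    excluded_socs: frozenset[str] = DEFAULT_EXCLUDED_SOCS

    def __contains__(self, soc: str) -> bool:
        return soc in self.excluded_socs


@dataclass
class MedDRAHierarchy:
    """PT -> primary HLT -> HLGT -> primary SOC maps plus SMQ term sets.

    Invariants (verified by :func:`load_hierarchy` and :meth:`validate`):
    every PT maps to exactly one primary HLT, every HLT to exactly one
    HLGT and one primary SOC, and for each SMQ the narrow term set is a
    subset of the broad set.
    """

    pt_to_primary_hlt: dict[str, str]
    hlt_to_hlgt: dict[str, str]
    hlt_to_primary_soc: dict[str, str]
    smq_terms: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)
    term_names: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        for hlt in set(self.pt_to_primary_hlt.values()):
            if hlt not in self.hlt_to_primary_soc:
                raise HierarchyIntegrityError(f"HLT {hlt!r} has no primary SOC")
            if hlt not in self.hlt_to_hlgt:
                raise HierarchyIntegrityError(f"HLT {hlt!r} has no HLGT")
        for name in {k[0] for k in self.smq_terms}:
            narrow = self.smq_terms.get((name, "narrow"), frozenset())
            broad = self.smq_terms.get((name, "broad"), frozenset())
            if broad and not narrow <= broad:
                missing = sorted(narrow - broad)
                raise HierarchyIntegrityError(
                    f"SMQ {name!r}: narrow terms {missing} missing from broad scope"
                )

    def smq(self, smq_name: str, scope: str = "narrow") -> frozenset[str]:
        """Return the PT set of an SMQ at the given scope.

        The broad scope of an SMQ always includes its narrow terms, even if
        the broad rows list only the additional ones.
        """
        if scope not in ("narrow", "broad"):
            raise ValueError(f"scope must be 'narrow' or 'broad', got {scope!r}")
        names = {k[0] for k in self.smq_terms}
        if smq_name not in names:
            raise KeyError(f"unknown SMQ {smq_name!r}; available: {sorted(names)}")
        narrow = self.smq_terms.get((smq_name, "narrow"), frozenset())
        if scope == "narrow":
            return narrow
        return narrow | self.smq_terms.get((smq_name, "broad"), frozenset())

    def name_of(self, code: str) -> str:
        return self.term_names.get(code, code)


def load_hierarchy(path: str | Path, smq_path: str | Path | None = None) -> MedDRAHierarchy:
    """Load a hierarchy from the dictionary TSV dialect, verifying invariants.

    Parameters
    ----------
    path
        Dictionary TSV (columns ``pt``, ``primary_hlt``, ``hlgt``,
        ``primary_soc``; optional ``*_name`` display columns).
    smq_path
        Optional SMQ TSV (columns ``smq_name``, ``scope``, ``pt``).  An
        empty or absent file yields a hierarchy with no SMQ terms.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"pt", "primary_hlt", "hlgt", "primary_soc"}
    missing = required - set(df.columns)
    if missing:
        raise HierarchyIntegrityError(
            f"dictionary {path} missing required columns: {sorted(missing)}"
        )

    pt_to_hlt: dict[str, str] = {}
    hlt_to_hlgt: dict[str, str] = {}
    hlt_to_soc: dict[str, str] = {}
    names: dict[str, str] = {}
    for row in df.itertuples(index=False):
        pt, hlt, hlgt, soc = row.pt, row.primary_hlt, row.hlgt, row.primary_soc
        if pt in pt_to_hlt and pt_to_hlt[pt] != hlt:
            raise HierarchyIntegrityError(
                f"PT {pt!r} maps to two primary HLTs: {pt_to_hlt[pt]!r} and {hlt!r}"
            )
        if hlt in hlt_to_soc and hlt_to_soc[hlt] != soc:
            raise HierarchyIntegrityError(
                f"HLT {hlt!r} maps to two primary SOCs: {hlt_to_soc[hlt]!r} and {soc!r}"
            )
        if hlt in hlt_to_hlgt and hlt_to_hlgt[hlt] != hlgt:
            raise HierarchyIntegrityError(
                f"HLT {hlt!r} maps to two HLGTs: {hlt_to_hlgt[hlt]!r} and {hlgt!r}"
            )
        pt_to_hlt[pt] = hlt
        hlt_to_hlgt[hlt] = hlgt
        hlt_to_soc[hlt] = soc
        for code_col, name_col in (("pt", "pt_name"), ("primary_hlt", "hlt_name"), ("hlgt", "hlgt_name")):
            if name_col in df.columns:
                names[getattr(row, code_col)] = getattr(row, name_col)

    smq_terms: dict[tuple[str, str], frozenset[str]] = {}
    if smq_path is not None:
        sdf = pd.read_csv(smq_path, sep="\t", dtype=str, keep_default_na=False)
        if len(sdf):
            req = {"smq_name", "scope", "pt"}
            if not req <= set(sdf.columns):
                raise HierarchyIntegrityError(
                    f"SMQ file {smq_path} missing columns: {sorted(req - set(sdf.columns))}"
                )
            for (name, scope), grp in sdf.groupby(["smq_name", "scope"]):
                if scope not in ("narrow", "broad"):
                    raise HierarchyIntegrityError(
                        f"SMQ {name!r}: invalid scope {scope!r}"
                    )
                smq_terms[(name, scope)] = frozenset(grp["pt"])

    h = MedDRAHierarchy(pt_to_hlt, hlt_to_hlgt, hlt_to_soc, smq_terms, names)
    h.validate()
    return h


def project_to_hlt(
    reaction_pts,
    hierarchy: MedDRAHierarchy,
    exclusions: SOCExclusionList | frozenset[str] | None = None,
    skip_log: list[str] | None = None,
) -> frozenset[str]:
    """Project a report's reaction PTs onto their primary HLTs.

    Each PT maps to its single primary HLT; HLTs whose primary SOC is in
    ``exclusions`` are dropped, and unknown PTs are logged and skipped
    (real spontaneous-report data contains verbatim and retired terms).
    The result is a set: a report contributes at most once per HLT no
    matter how many of its PTs map there.

    ``reaction_pts`` may be a PT iterable or any object with a
    ``reaction_pts`` attribute (a report record).
    """
    if hasattr(reaction_pts, "reaction_pts"):
        reaction_pts = reaction_pts.reaction_pts
    if exclusions is None:
        excluded: frozenset[str] = DEFAULT_EXCLUDED_SOCS
    elif isinstance(exclusions, SOCExclusionList):
        excluded = exclusions.excluded_socs
    else:
        excluded = frozenset(exclusions)

    hlts: set[str] = set()
    for pt in reaction_pts:
        hlt = hierarchy.pt_to_primary_hlt.get(pt)
        if hlt is None:
            logger.info("unknown PT skipped: %s", pt)
            if skip_log is not None:
                skip_log.append(pt)
            continue
        if hierarchy.hlt_to_primary_soc[hlt] in excluded:
            continue
        hlts.add(hlt)
    return frozenset(hlts)
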