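"""Replication-filtered basetype curation and basegroup assembly.

The molecular nomenclature rests on two filters applied to raw Sanger
reads of the ~1000 bp SSU rDNA barcode fragment:

1. a *replication* filter — a sequence motif is only trusted as a
   basetype if the identical motif was observed at least
   ``min_replication`` times (default 3) across the dataset, which
   screens out sequencing errors; and
2. a *co-occurrence* filter — basetypes observed together within the
   same individual (intragenomic rRNA copy variants) are merged into a
   basegroup, but only when the co-occurrence is witnessed by at least
   ``min_cooccurrence_individuals`` distinct individuals (default 2),
   which screens out contamination and PCR chimeras.

Reads that fail the quality bar (``quality == "partial"``) never define
basetypes; they are attributed post hoc to the finest MOTU whose
diagnostic sites their covered region contains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SequenceRecord",
    "Basetype",
    "Basegroup",
    "DiagnosticSiteTable",
    "filter_replicated",
    "extract_basetypes",
    "assemble_basegroups",
    "compute_diagnostic_sites",
    "attribute_partial",
]

_AMBIGUITY = set("RYSWKMBDHVN")


@dataclass(frozen=True)
class SequenceRecord:
    """One barcode read with its collection metadata."""

    sequence_id: str
    individual_id: str
    station_id: str
    sequence: str
    morphospecies: str = ""
    date: str = ""
    latitude: float = 0.0
    longitude: float = 0.0
    depth_min: float = 0.0
    depth_max: float = 0.0
    quality: str = "curated"  # {curated, partial}
    source: str = "direct"  # {direct, clone}

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.sequence_id}: empty sequence")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"{self.sequence_id}: latitude out of range")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"{self.sequence_id}: longitude out of range")

    @property
    def motif(self) -> str:
        """Uppercased, gap-stripped comparison form of the sequence."""
        return normalize_motif(self.sequence)


def normalize_motif(sequence: str) -> str:
    return sequence.upper().replace("-", "").replace(".", "")


def records_from_frame(records: pd.DataFrame) -> list[SequenceRecord]:
    """Build SequenceRecord objects from a metadata+sequence DataFrame."""
    out = []
    for _, row in records.iterrows():
        out.append(
            SequenceRecord(
                sequence_id=str(row["sequence_id"]),
                individual_id=str(row["individual_id"]),
                station_id=str(row.get("station_id", "")),
                sequence=str(row["sequence"]),
                morphospecies=str(row.get("morphospecies", "")),
                date=str(row.get("date", "")),
                latitude=float(row.get("latitude", 0.0)),
                longitude=float(row.get("longitude", 0.0)),
                depth_min=float(row.get("depth_min", 0.0)),
                depth_max=float(row.get("depth_max", 0.0)),
                quality=str(row.get("quality", "curated")),
                source=str(row.get("source", "direct")),
            )
        )
    return out


@dataclass
class Basetype:
    basetype_id: str
    motif: str
    support: int
    members: list[str]


@dataclass
class Basegroup:
    basegroup_id: str
    basetypes: list[str]
    #: individual ids witnessing each accepted co-occurrence edge
    supporting_individuals: dict[tuple[str, str], list[str]] = field(
        default_factory=dict
    )


@dataclass
class DiagnosticSiteTable:
    """Per-level, per-taxon alignment columns with states unique to that
    taxon among its siblings.  Columns are 1-based."""

    #: level -> taxon label -> list of (column, state)
    sites: dict[str, dict[str, list[tuple[int, str]]]]
    warnings: list[str] = field(default_factory=list)


def filter_replicated(
    records: list[SequenceRecord], min_replication: int = 3
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Split reads into the curated (replicated) set and the attribution
    queue.

    A read enters the curated set when it is full quality and its motif
    occurs at least ``min_replication`` times among full-quality reads.
    Partial reads, and full reads of unreplicated motifs, go to the
    attribution path and never define basetypes.
    """
    if not records:
        logger.warning("filter_replicated: empty input")
        return [], []
    full = [r for r in records if r.quality == "curated"]
    partial = [r for r in records if r.quality != "curated"]
    counts: dict[str, int] = {}
    for r in full:
        counts[r.motif] = counts.get(r.motif, 0) + 1
    curated = [r for r in full if counts[r.motif] >= min_replication]
    unreplicated = [r for r in full if counts[r.motif] < min_replication]
    if unreplicated:
        logger.info(
            "filter_replicated: %d reads of unreplicated motifs routed to "
            "attribution", len(unreplicated)
        )
    return curated, partial + unreplicated


def extract_basetypes(curated: list[SequenceRecord]) -> list[Basetype]:
    """One basetype per distinct motif among the curated reads.

    Identity is exact string match after uppercasing and gap removal.
    IUPAC ambiguity codes are compared literally (with a warning).
    """
    by_motif: dict[str, list[SequenceRecord]] = {}
    for r in curated:
        by_motif.setdefault(r.motif, []).append(r)
    if any(set(m) & _AMBIGUITY for m in by_motif):
        logger.warning(
            "extract_basetypes: ambiguity codes present; compared literally"
        )
    # stable ids: decreasing support, then motif as tie-break
    ordered = sorted(
        by_motif.items(), key=lambda kv: (-len(kv[1]), kv[0])
    )
    out = []
    for i, (motif, members) in enumerate(ordered):
        out.append(
            Basetype(
                basetype_id=f"BT{i + 1:02d}",
                motif=motif,
                support=len(members),
                members=sorted(r.sequence_id for r in members),
            )
        )
    return out


def assemble_basegroups(
    basetypes: list[Basetype],
    records: list[SequenceRecord],
    min_cooccurrence_individuals: int = 2,
) -> tuple[list[Basegroup], list[dict]]:
    """Merge basetypes co-occurring within individuals into basegroups.

    An edge between two basetypes is accepted when they occur in the
    same individual in at least ``min_cooccurrence_individuals`` distinct
    individuals; basegroups are the connected components of the accepted
    edges.  Rejected single-individual co-occurrences are returned as a
    log of putative contamination events.
    """
    motif_to_bt = {bt.motif: bt.basetype_id for bt in basetypes}
    by_individual: dict[str, set[str]] = {}
    for r in records:
        bt = motif_to_bt.get(r.motif)
        if bt is not None and r.quality == "curated":
            by_individual.setdefault(r.individual_id, set()).add(bt)

    witnesses: dict[tuple[str, str], set[str]] = {}
    for ind, bts in by_individual.items():
        for a, b in combinations(sorted(bts), 2):
            witnesses.setdefault((a, b), set()).add(ind)

    graph = nx.Graph()
    graph.add_nodes_from(bt.basetype_id for bt in basetypes)
    rejected = []
    accepted_edges: dict[tuple[str, str], list[str]] = {}
    for (a, b), inds in sorted(witnesses.items()):
        if len(inds) >= min_cooccurrence_individuals:
            graph.add_edge(a, b)
            accepted_edges[(a, b)] = sorted(inds)
        else:
            rejected.append(
                {"basetypes": [a, b], "individuals": sorted(inds),
                 "reason": "single-individual co-occurrence"}
            )
            logger.info(
                "assemble_basegroups: rejected co-occurrence %s-%s "
                "(witnessed only by %s)", a, b, sorted(inds)
            )

    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)),
        key=lambda c: c[0],
    )
    groups = []
    for i, comp in enumerate(components):
        edges = {
            e: w for e, w in accepted_edges.items()
            if e[0] in comp and e[1] in comp
        }
        groups.append(
            Basegroup(
                basegroup_id=f"BG{i + 1:02d}",
                basetypes=comp,
                supporting_individuals=edges,
            )
        )
    return groups, rejected


# ---------------------------------------------------------------------------
# diagnostic sites and attribution of partial reads


def compute_diagnostic_sites(
    alignment: dict[str, str],
    labels: dict[str, dict[str, str]],
) -> DiagnosticSiteTable:
    """Columns whose state separates one taxon from all of its siblings.

    ``alignment`` maps basetype_id -> aligned motif (equal lengths);
    ``labels`` maps level name -> {basetype_id -> taxon label}, coarsest
    level first.  At each level, siblings are the taxa sharing the same
    parent label at the preceding level (all taxa at the first level).
    A column is diagnostic for a taxon when all member basetypes agree
    on a state that no sibling basetype carries.
    """
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) > 1:
        raise ValueError("alignment rows have unequal lengths")
    ncol = lengths.pop() if lengths else 0
    warnings: list[str] = []
    level_names = list(labels)
    sites: dict[str, dict[str, list[tuple[int, str]]]] = {}
    for li, level in enumerate(level_names):
        lab = labels[level]
        parent = labels[level_names[li - 1]] if li else None
        sites[level] = {}
        # sibling families share the parent label
        families: dict[str, set[str]] = {}
        for bt, taxon in lab.items():
            key = parent[bt] if parent else ""
            families.setdefault(key, set()).add(taxon)
        for famkey, taxa in sorted(families.items()):
            if len(taxa) < 2:
                continue  # nothing to diagnose against
            members = {
                t: [bt for bt, l in lab.items()
                    if l == t and (parent is None or parent[bt] == famkey)]
                for t in taxa
            }
            for taxon in sorted(taxa):
                own = members[taxon]
                others = [bt for t in taxa if t != taxon
                          for bt in members[t]]
                found: list[tuple[int, str]] = []
                for col in range(ncol):
                    states = {alignment[bt][col] for bt in own}
                    if len(states) != 1:
                        continue
                    state = states.pop()
                    if all(alignment[bt][col] != state for bt in others):
                        found.append((col + 1, state))
                sites[level][taxon] = found
                if not found:
                    warnings.append(
                        f"{level}/{taxon}: no diagnostic site among siblings"
                    )
    return DiagnosticSiteTable(sites=sites, warnings=warnings)


def _map_to_reference(fragment: str, alignment: dict[str, str]) -> tuple[int, str] | None:
    """Place a contiguous fragment onto reference coordinates.

    Partial reads are prefix/suffix truncations without indels, so the
    placement is the offset minimizing mismatches against the closest
    reference motif.  Returns (0-based offset, best reference id), or
    None when nothing aligns better than 75% identity.
    """
    frag = normalize_motif(fragment)
    ncol = len(next(iter(alignment.values())))
    if len(frag) > ncol:
        return None
    best = None
    for ref_id, ref in alignment.items():
        for off in (0, ncol - len(frag)):  # prefix or suffix placement
            window = ref[off:off + len(frag)]
            mism = sum(a != b for a, b in zip(frag, window))
            if best is None or mism < best[0]:
                best = (mism, off, ref_id)
    if best is None or best[0] > 0.25 * len(frag):
        return None
    return best[1], best[2]


def attribute_partial(
    record: SequenceRecord,
    table: DiagnosticSiteTable,
    alignment: dict[str, str],
    labels: dict[str, dict[str, str]] | None = None,
) -> dict:
    """Attribute a partial read to the finest MOTU its coverage allows.

    Walks the levels from coarsest to finest; at each level the covered
    diagnostic sites must point at exactly one taxon (among the children
    of the previous assignment) and contradict none of its own sites.
    Conflicting diagnostic states abort with ``unassigned``.  Returns a
    dict with ``level``, ``label``, ``evidence`` (matched sites) and
    ``conflicts``.
    """
    placement = _map_to_reference(record.sequence, alignment)
    result = {"sequence_id": record.sequence_id, "level": None,
              "label": "unassigned", "evidence": [], "conflicts": []}
    if placement is None:
        return result
    off, _ = placement
    frag = normalize_motif(record.sequence)
    covered = range(off + 1, off + len(frag) + 1)  # 1-based columns

    def frag_state(col: int) -> str:
        return frag[col - 1 - off]

    parent_level = None
    parent_label = None
    level_names = list(table.sites)
    for li, level in enumerate(level_names):
        # restrict candidates to children of the current assignment
        if labels is not None and parent_label is not None:
            parent_map = labels[level_names[li - 1]]
            level_map = labels[level]
            allowed = {
                level_map[bt] for bt in level_map
                if parent_map.get(bt) == parent_label
            }
        else:
            allowed = set(table.sites[level])
        if labels is not None and len(allowed) == 1:
            # single child under the current assignment: implied
            taxon = next(iter(allowed))
            result.update(level=level, label=taxon)
            parent_level, parent_label = level, taxon
            continue
        matched: dict[str, list[tuple[int, str]]] = {}
        contradicted: set[str] = set()
        for taxon, tsites in table.sites[level].items():
            if taxon not in allowed:
                continue
            hits = []
            for col, state in tsites:
                if col in covered:
                    if frag_state(col) == state:
                        hits.append((col, state))
                    else:
                        contradicted.add(taxon)
            if hits:
                matched[taxon] = hits
        candidates = {t: h for t, h in matched.items()
                      if t not in contradicted}
        if len(candidates) == 1:
            taxon, hits = next(iter(candidates.items()))
            result.update(level=level, label=taxon)
            result["evidence"].extend(
                {"level": level, "column": c, "state": s} for c, s in hits
            )
            parent_level, parent_label = level, taxon
        else:
            # ambiguity (several clean candidates) or contradiction:
            # stop here, keeping the previous (coarser) assignment
            if len(candidates) > 1:
                result["conflicts"].append(
                    {"level": level, "taxa": sorted(candidates)}
                )
            elif matched and contradicted:
                result["conflicts"].append(
                    {"level": level, "taxa": sorted(contradicted)}
                )
            break
    return result
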