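"""Search jobs over target directories and tabular result output.

Maps the three search objectives onto engine runs: annotating one
structure with a motif library, scanning many structures for one query,
and hydrogen-bond cluster pattern scans / two-structure comparisons.
Targets that fail to parse are skipped with a warning, never abort a
scan; results are deduplicated per site, globally ranked, and written as
a deterministic CSV.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np

from .graph_search import (
    ClusterPattern,
    Engine,
    MotifQuery,
    SearchMode,
    ToleranceConfig,
    clique_partial_match,
    compare_structures_by_clusters,
    match_cluster_pattern,
    ullmann_match,
)
from .representation import (
    PseudoAtomMode,
    build_connection_table,
    detect_hydrogen_bonds,
    structure_pseudoatoms,
)
from .structure_io import (
    ResidueKind,
    Structure,
    StructureError,
    list_het_neighbors,
    load_structure,
)
from .superpose import (
    ChainFilter,
    Match,
    dedupe_matches,
    rank_and_filter,
    score_match,
)

log = logging.getLogger(__name__)


class JobError(RuntimeError):
    """The job as a whole cannot run (e.g. no readable target)."""


class SearchObjective(Enum):
    MOTIF_IN_STRUCTURE = "MOTIF_IN_STRUCTURE"  # motif library vs one structure
    STRUCTURE_DB_SCAN = "STRUCTURE_DB_SCAN"    # one query vs many structures
    CLUSTER_SCAN = "CLUSTER_SCAN"              # connection-pattern search


@dataclass
class SearchJob:
    objective: SearchObjective
    queries: list[tuple[str, MotifQuery | ClusterPattern]]
    target_paths: list[Path]
    tol: ToleranceConfig = field(default_factory=ToleranceConfig)
    min_size: int = 3
    max_rmsd: float | None = None
    require_het: bool = False
    chain_filter: str = ChainFilter.ANY
    resolution_cutoff: float | None = None
    het_cutoff: float = 4.0

    def __post_init__(self) -> None:
        for _, q in self.queries:
            if isinstance(q, ClusterPattern) and self.objective is not SearchObjective.CLUSTER_SCAN:
                raise JobError("cluster patterns are only valid for CLUSTER_SCAN jobs")


@dataclass
class ResultRow:
    query_id: str
    target_id: str
    residues: str       # semicolon-joined chain:resnum:name identifiers
    composition: str
    matched_size: int
    rmsd: float | None
    same_chain: bool
    near_het: bool
    engine: str
    tolerance: str


CSV_COLUMNS = [
    "query_id",
    "target_id",
    "residues",
    "composition",
    "matched_size",
    "rmsd",
    "same_chain",
    "near_het",
    "engine",
    "tolerance",
]


def _tolerance_label(q: MotifQuery | ClusterPattern, tol: ToleranceConfig) -> str:
    if isinstance(q, ClusterPattern):
        return "-"
    if q.mode is SearchMode.RNA:
        return f"{tol.rna_frac_tol * 100:.0f}%"
    return f"{tol.protein_abs_tol:.2f}A"


def _row_from_match(
    query_id: str, q: MotifQuery | ClusterPattern, m: Match, tol: ToleranceConfig
) -> ResultRow:
    return ResultRow(
        query_id=query_id,
        target_id=m.target_id,
        residues=";".join(r.ident for r in m.matched_residues),
        composition=m.composition,
        matched_size=m.matched_size,
        rmsd=m.rmsd,
        same_chain=m.same_chain,
        near_het=m.near_het,
        engine=(
            q.engine.value if isinstance(q, MotifQuery) and q.residues else "CLUSTER"
        ),
        tolerance=_tolerance_label(q, tol),
    )


def _cluster_matches(
    pattern: ClusterPattern, s: Structure, het_cutoff: float
) -> list[Match]:
    bonds = detect_hydrogen_bonds(s)
    ct = build_connection_table(s, bonds)
    out = []
    for a in match_cluster_pattern(pattern, ct):
        residues = [a.mapping[i].residue for i in sorted(a.mapping)]
        positions = np.array([at.pos for r in residues for at in r.atoms])
        chains = {r.chain_id for r in residues}
        out.append(
            Match(
                assignment=a,
                superposition=None,
                target_id=s.id,
                same_chain=len(chains) == 1,
                near_het=list_het_neighbors(s, positions, cutoff=het_cutoff),
            )
        )
    return out


def _geometry_matches(
    q: MotifQuery, s: Structure, job: SearchJob
) -> list[Match]:
    kind = ResidueKind.AMINO if q.mode is SearchMode.PROTEIN else ResidueKind.BASE
    nodes = structure_pseudoatoms(s, kind, q.pair_mode)
    if not nodes:
        return []
    if q.engine is Engine.PARTIAL:
        assignments = clique_partial_match(q, nodes, job.tol, min_size=job.min_size)
    else:
        assignments = ullmann_match(q, nodes, job.tol)
    if q.is_hypothetical:
        # no geometry to rank mappings by: collapse automorphic mappings early
        seen, unique = set(), []
        for a in assignments:
            if a.residue_set not in seen:
                seen.add(a.residue_set)
                unique.append(a)
        assignments = unique
    return [score_match(a, q, s, het_cutoff=job.het_cutoff) for a in assignments]


def run_search(job: SearchJob) -> list[ResultRow]:
    """Execute a job: load → represent → match → score → filter → rank.

    Unreadable targets are logged and skipped; a resolution cutoff skips
    targets whose recorded resolution is worse (numerically larger).
    Raises :class:`JobError` if no target could be read at all.
    """
    if not job.queries:
        raise JobError("job defines no queries")
    rows: list[ResultRow] = []
    n_readable = 0
    for path in sorted(job.target_paths, key=lambda p: Path(p).name):
        try:
            s = load_structure(path)
        except StructureError as exc:
            log.warning("skipping unreadable target %s: %s", path, exc)
            continue
        n_readable += 1
        if (
            job.resolution_cutoff is not None
            and s.resolution is not None
            and s.resolution > job.resolution_cutoff
        ):
            log.info(
                "skipping %s: resolution %.2f worse than cutoff %.2f",
                s.id, s.resolution, job.resolution_cutoff,
            )
            continue
        for query_id, q in job.queries:
            if isinstance(q, ClusterPattern):
                matches = _cluster_matches(q, s, job.het_cutoff)
            else:
                matches = _geometry_matches(q, s, job)
            matches = dedupe_matches(matches)
            matches = rank_and_filter(
                matches,
                max_rmsd=job.max_rmsd,
                require_het=job.require_het,
                chain_filter=job.chain_filter,
            )
            rows.extend(_row_from_match(query_id, q, m, job.tol) for m in matches)
            log.info("%s vs %s: %d hit(s)", query_id, s.id, len(matches))
    if n_readable == 0:
        raise JobError("no readable target structures")
    rows.sort(
        key=lambda r: (
            r.rmsd if r.rmsd is not None else float("inf"),
            -r.matched_size,
            r.target_id,
            r.residues,
            r.query_id,
        )
    )
    return rows


def run_cluster_comparison(
    path1: Path, path2: Path, size_range: tuple[int, int] = (2, 6)
):
    """Compare the hydrogen-bonded clusters of two structures."""
    tables = []
    for p in (path1, path2):
        s = load_structure(p)
        tables.append(build_connection_table(s, detect_hydrogen_bonds(s)))
    return compare_structures_by_clusters(tables[0], tables[1], size_range)


def format_results_csv(rows: Sequence[ResultRow]) -> str:
    """Render rows to CSV text (RMSD to 2 decimals; deterministic bytes)."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(CSV_COLUMNS)
    for r in rows:
        writer.writerow(
            [
                r.query_id,
                r.target_id,
                r.residues,
                r.composition,
                r.matched_size,
                "" if r.rmsd is None else f"{r.rmsd:.2f}",
                str(r.same_chain).lower(),
                str(r.near_het).lower(),
                r.engine,
                r.tolerance,
            ]
        )
    return buf.getvalue()


def write_results_csv(rows: Sequence[ResultRow], path: str | Path) -> None:
    Path(path).write_text(format_results_csv(rows))
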