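"""Iterative non-redundant query selection and family profile building.

A single seed protein rarely detects remote family members, so each
family's profile is built from a broadened query set: starting from the
seed, the current query is searched against the remaining protein pool;
among hits below the E-value threshold whose global identity to *every*
already-selected query is below the redundancy threshold (default 97%),
the lowest-E hit becomes the next query and is removed from the pool.
With the default 20 rounds this yields up to 21 queries per family, which
are multiply aligned and compiled into a profile HMM.
"""

from __future__ import annotations

import io
import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .genome_model import Config
from .seqsearch import (
    EvalueCalibration,
    PairwiseSearchEngine,
    ProfileModel,
    SearchError,
    build_profile,
    global_identity,
)

logger = logging.getLogger(__name__)


@dataclass
class QuerySet:
    """Ordered queries for one family; the first entry is the initial seed."""

    family: str
    queries: list[tuple[str, str]]  # (id, sequence)
    rounds_executed: int
    exhausted_early: bool

    @property
    def ids(self) -> list[str]:
        return [qid for qid, _ in self.queries]

    @property
    def sequences(self) -> list[str]:
        return [seq for _, seq in self.queries]

    def __len__(self) -> int:
        return len(self.queries)


def select_queries(
    seed: str,
    family: str,
    db: dict[str, str],
    cfg: Config = Config(),
    engine: PairwiseSearchEngine | None = None,
    seed_id: str | None = None,
) -> QuerySet:
    """Iterative selection of up to ``cfg.selection_rounds`` extra queries.

    Each round searches the current query against the remaining pool
    (E < ``cfg.evalue_threshold``); candidates at >= ``cfg.identity_threshold``
    global identity to any already-selected query are excluded, and the
    lowest-E survivor (ties: higher score, then lexicographic id) is
    selected and removed from the pool.  Stops early when no candidate is
    eligible.
    """
    if not seed:
        raise SearchError("seed sequence is empty")
    seed_id = seed_id or f"{family}__seed"
    if engine is None:
        engine = PairwiseSearchEngine()
    if engine.calibration is None:
        if not db:
            return QuerySet(family, [(seed_id, seed)], 0, True)
        engine.calibrate(db, seed=cfg.rng_seed)

    pool = {gid: s for gid, s in db.items() if gid != seed_id}
    selected: list[tuple[str, str]] = [(seed_id, seed)]
    current = seed
    rounds = 0
    exhausted = False
    for _ in range(cfg.selection_rounds):
        if not pool:
            exhausted = True
            break
        hits = engine.search(current, pool, cfg.evalue_threshold, family=family)
        chosen = None
        for h in hits:  # sorted by (evalue, -score, id)
            cand = pool[h.target_gene_id]
            if all(
                global_identity(cand, q) < cfg.identity_threshold
                for _, q in selected
            ):
                chosen = (h.target_gene_id, cand)
                break
        if chosen is None:
            exhausted = True
            break
        selected.append(chosen)
        del pool[chosen[0]]
        current = chosen[1]
        rounds += 1
    return QuerySet(
        family=family,
        queries=selected,
        rounds_executed=rounds,
        exhausted_early=exhausted,
    )


def align_queries(
    queries: list[tuple[str, str]], mafft_path: str | None = None
) -> list[tuple[str, str]]:
    """Multiple alignment of the query set (MAFFT; trivial for one query)."""
    if not queries:
        raise SearchError("no queries to align")
    if len(queries) == 1:
        return list(queries)
    exe = mafft_path or shutil.which("mafft")
    if exe is None:
        raise SearchError("mafft executable not found")
    with tempfile.TemporaryDirectory() as tmp:
        infile = Path(tmp) / "in.fa"
        with open(infile, "w") as fh:
            for qid, seq in queries:
                fh.write(f">{qid}\n{seq}\n")
        proc = subprocess.run(
            [exe, "--quiet", "--auto", str(infile)],
            capture_output=True,
            text=True,
            check=True,
        )
    aligned = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(io.StringIO(proc.stdout), "fasta")
    }
    # preserve the original query order
    return [(qid, aligned[qid]) for qid, _ in queries]


def family_profile(
    qs: QuerySet,
    cal: EvalueCalibration | None = None,
    mafft_path: str | None = None,
) -> ProfileModel:
    """Align the selected queries and compile the family profile HMM."""
    try:
        aligned = align_queries(qs.queries, mafft_path=mafft_path)
        return build_profile(aligned, family=qs.family)
    except Exception as exc:
        raise SearchError(f"profile construction failed for {qs.family}: {exc}") from exc


def write_queries_fasta(qs: QuerySet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for qid, seq in qs.queries:
            fh.write(f">{qid}\n{seq}\n")
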