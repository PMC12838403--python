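"""Sequence-search engine: pairwise alignment and profile searches.

Two search paths feed the pipeline:

* a **pairwise** path (Smith–Waterman / Needleman–Wunsch with BLOSUM62 and
  affine gaps, via :class:`Bio.Align.PairwiseAligner`) used by the
  iterative query-selection loop.  Its raw scores carry no statistics, so
  full-sequence E-values are obtained from a seeded Gumbel
  (Karlin–Altschul-style) calibration against shuffled decoys;
* a **profile** path (profile HMMs built from the selected, aligned
  queries and searched with full-sequence E-values, via pyhmmer) used for
  the genome-wide family scan.

Both paths report hits the same way (:class:`SearchHit`) and apply the
same full-sequence E-value threshold, so family assignment downstream is
agnostic to the backend.
"""

from __future__ import annotations

import datetime
import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pyhmmer
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AMINO_ACIDS + "X"


class SearchError(ValueError):
    pass


def _blosum62_with_x() -> substitution_matrices.Array:
    """BLOSUM62 over the 20 amino acids, with X scoring 0 against everything."""
    src = substitution_matrices.load("BLOSUM62")
    mat = substitution_matrices.Array(alphabet=ALPHABET, dims=2)
    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            mat[a, b] = src[a, b]
    return mat


@dataclass(frozen=True)
class SubstitutionModel:
    """Scoring scheme for pairwise protein alignment.

    Penalties follow the BLAST convention: a gap of length k costs
    ``gap_open + k * gap_extend``.
    """

    gap_open: int = 11
    gap_extend: int = 1
    score_matrix: substitution_matrices.Array = field(
        default_factory=_blosum62_with_x, compare=False
    )

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")

    def aligner(self, mode: str) -> Align.PairwiseAligner:
        al = Align.PairwiseAligner()
        al.mode = mode
        al.substitution_matrix = self.score_matrix
        al.open_gap_score = -(self.gap_open + self.gap_extend)
        al.extend_gap_score = -self.gap_extend
        return al


DEFAULT_MODEL = SubstitutionModel()


@dataclass(frozen=True)
class AlignmentResult:
    score: float
    identity_pct: float
    aligned_length: int
    query_coverage: float


@dataclass(frozen=True)
class SearchHit:
    """A scored match of one target protein against a query or profile."""

    target_gene_id: str
    family: str
    score: float
    evalue: float
    identity_to_query_pct: float | None = None

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError("evalue must be > 0")


def _sanitize(seq: str, what: str) -> str:
    if not seq:
        raise SearchError(f"{what} sequence is empty")
    seq = seq.upper()
    if any(c not in ALPHABET for c in seq):
        bad = sorted({c for c in seq if c not in ALPHABET})
        logger.warning("%s: residues %s mapped to X", what, "".join(bad))
        seq = "".join(c if c in ALPHABET else "X" for c in seq)
    return seq


def _identity_from_alignment(aln: Align.Alignment) -> tuple[float, int]:
    """Percent identity over all alignment columns (gap columns count)."""
    counts = aln.counts()
    ncol = aln.shape[1]
    return 100.0 * counts.identities / ncol, ncol


def local_align(
    query: str, target: str, model: SubstitutionModel = DEFAULT_MODEL
) -> AlignmentResult:
    """Optimal affine-gap local (Smith–Waterman) alignment."""
    query = _sanitize(query, "query")
    target = _sanitize(target, "target")
    alns = model.aligner("local").align(query, target)
    if len(alns) == 0 or alns.score <= 0:
        # no residue pair scores positive: the optimal local alignment is empty
        return AlignmentResult(
            score=0.0, identity_pct=0.0, aligned_length=0, query_coverage=0.0
        )
    aln = alns[0]
    identity, ncol = _identity_from_alignment(aln)
    qspan = aln.coordinates[0, -1] - aln.coordinates[0, 0]
    return AlignmentResult(
        score=float(aln.score),
        identity_pct=identity,
        aligned_length=ncol,
        query_coverage=float(qspan) / len(query),
    )


def global_align(
    a: str, b: str, model: SubstitutionModel = DEFAULT_MODEL
) -> AlignmentResult:
    """Needleman–Wunsch global alignment; identity over full alignment length.

    Arguments are ordered canonically before aligning so that the reported
    identity is symmetric even when co-optimal alignments differ.
    """
    a = _sanitize(a, "a")
    b = _sanitize(b, "b")
    if (len(a), a) > (len(b), b):
        a, b = b, a
    aln = model.aligner("global").align(a, b)[0]
    identity, ncol = _identity_from_alignment(aln)
    return AlignmentResult(
        score=float(aln.score),
        identity_pct=identity,
        aligned_length=ncol,
        query_coverage=1.0,
    )


def global_identity(
    a: str, b: str, model: SubstitutionModel = DEFAULT_MODEL
) -> float:
    return global_align(a, b, model).identity_pct


# ---------------------------------------------------------------------------
# E-value calibration for the pairwise path
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EvalueCalibration:
    """Gumbel (extreme-value) null fit for local-alignment scores.

    E(S) = K * m * N * exp(-lambda * S) for a query of length m against a
    database of N residues; lambda and K are fitted from scores of
    shuffled-decoy alignments.
    """

    lam: float
    K: float
    database_size: int
    decoy_count: int
    rng_seed: int

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be > 0")

    def evalue(
        self, score: float, query_len: int, database_size: int | None = None
    ) -> float:
        n = self.database_size if database_size is None else database_size
        e = self.K * query_len * n * math.exp(-self.lam * score)
        return max(e, 1e-300)


def calibrate_evalues(
    model: SubstitutionModel,
    db: Mapping[str, str] | Sequence[str],
    decoys: int = 200,
    seed: int = 0,
) -> EvalueCalibration:
    """Fit Gumbel parameters from local alignments of shuffled db sequences.

    Pairs of database sequences are residue-shuffled (composition kept) and
    locally aligned; the resulting score distribution is fitted with a
    right-skewed Gumbel whose location/scale give K and lambda.
    """
    seqs = list(db.values()) if isinstance(db, Mapping) else list(db)
    if not seqs:
        raise SearchError("cannot calibrate against an empty database")
    if decoys < 50:
        raise SearchError("need at least 50 decoys for a stable fit")
    rng = np.random.default_rng(seed)
    total_residues = sum(len(s) for s in seqs)
    scores = []
    mn = []
    for _ in range(decoys):
        i, j = rng.integers(0, len(seqs), size=2)
        a = "".join(rng.permutation(list(seqs[i])))
        b = "".join(rng.permutation(list(seqs[j])))
        aln = model.aligner("local").align(_sanitize(a, "decoy"), _sanitize(b, "decoy"))
        scores.append(float(aln.score))
        mn.append(len(a) * len(b))
    scores = np.asarray(scores)
    if np.ptp(scores) == 0:
        raise SearchError("degenerate decoy score distribution (all scores equal)")
    loc, scale = stats.gumbel_r.fit(scores)
    lam = 1.0 / scale
    K = math.exp(loc / scale) / float(np.mean(mn))
    return EvalueCalibration(
        lam=lam,
        K=K,
        database_size=total_residues,
        decoy_count=decoys,
        rng_seed=seed,
    )


class PairwiseSearchEngine:
    """BLAST-like search of one query against a protein collection."""

    def __init__(
        self,
        model: SubstitutionModel = DEFAULT_MODEL,
        calibration: EvalueCalibration | None = None,
    ):
        self.model = model
        self.calibration = calibration

    def calibrate(self, db: Mapping[str, str], decoys: int = 200, seed: int = 0):
        self.calibration = calibrate_evalues(self.model, db, decoys, seed)
        return self.calibration

    def search(
        self,
        query: str,
        db: Mapping[str, str],
        threshold: float,
        family: str = "",
    ) -> list[SearchHit]:
        if self.calibration is None:
            raise SearchError("engine is not calibrated")
        hits = []
        for gene_id in sorted(db):
            res = local_align(query, db[gene_id], self.model)
            ev = self.calibration.evalue(res.score, len(query))
            if ev < threshold:
                hits.append(
                    SearchHit(
                        target_gene_id=gene_id,
                        family=family,
                        score=res.score,
                        evalue=ev,
                        identity_to_query_pct=res.identity_pct,
                    )
                )
        hits.sort(key=lambda h: (h.evalue, -h.score, h.target_gene_id))
        return hits


# ---------------------------------------------------------------------------
# Profile path (profile HMMs)
# ---------------------------------------------------------------------------

_AA_ALPHABET = pyhmmer.easel.Alphabet.amino()


@dataclass
class ProfileModel:
    """Position-specific scoring model built from aligned queries.

    Wraps a plan7 profile HMM: match states are the alignment columns with
    <50% gaps, with pseudocount-smoothed emissions scored as log-odds
    against background residue frequencies.
    """

    hmm: pyhmmer.plan7.HMM
    family: str
    source_query_ids: list[str]

    @property
    def match_columns(self) -> int:
        return self.hmm.M

    def match_emissions(self) -> np.ndarray:
        """(M+1) x 20 match-state emission probabilities (row 0 is unused)."""
        return np.asarray(self.hmm.match_emissions)

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            self.hmm.write(fh, binary=False)

    @classmethod
    def load(cls, path: str | Path, family: str = "") -> "ProfileModel":
        with pyhmmer.plan7.HMMFile(str(path)) as hf:
            hmm = hf.read()
        raw = hmm.name
        name = family or (raw if isinstance(raw, str) else raw.decode())
        return cls(hmm=hmm, family=name, source_query_ids=[])


def build_profile(
    queries: Sequence[tuple[str, str]], family: str = "profile"
) -> ProfileModel:
    """Build a profile HMM from aligned sequences of equal length.

    ``queries`` is an ordered collection of (id, aligned_sequence); gaps are
    '-' or '.'.  Columns with <50% gap fraction become match columns.
    """
    if not queries:
        raise SearchError("cannot build a profile from zero sequences")
    lengths = {len(s) for _, s in queries}
    if len(lengths) != 1:
        raise SearchError("aligned queries must all have the same length")
    if all(set(s) <= {"-", "."} for _, s in queries):
        raise SearchError("alignment has zero match columns")
    text = pyhmmer.easel.TextMSA(
        name=family.encode(),
        sequences=[
            pyhmmer.easel.TextSequence(name=qid.encode(), sequence=seq.upper())
            for qid, seq in queries
        ],
    )
    digital = text.digitize(_AA_ALPHABET)
    builder = pyhmmer.plan7.Builder(_AA_ALPHABET, seed=42)
    background = pyhmmer.plan7.Background(_AA_ALPHABET)
    hmm, _, _ = builder.build_msa(digital, background)
    # pin the creation timestamp so serialized profiles are reproducible
    hmm.creation_time = datetime.datetime(2000, 1, 1)
    return ProfileModel(
        hmm=hmm, family=family, source_query_ids=[qid for qid, _ in queries]
    )


def _digital_db(db: Mapping[str, str]) -> pyhmmer.easel.DigitalSequenceBlock:
    seqs = [
        pyhmmer.easel.TextSequence(name=gene_id.encode(), sequence=_sanitize(seq, gene_id))
        for gene_id, seq in sorted(db.items())
    ]
    return pyhmmer.easel.TextSequenceBlock(seqs).digitize(_AA_ALPHABET)


def profile_search(
    profile: ProfileModel,
    db: Mapping[str, str],
    threshold: float = 1e-5,
    calibration: EvalueCalibration | None = None,
) -> list[SearchHit]:
    """Search a profile against a protein collection.

    Returns hits whose full-sequence E-value is < ``threshold``, sorted by
    E-value ascending then gene id.  E-values come from the profile's own
    calibrated statistics with the database size fixed to the number of
    target sequences; ``calibration`` is accepted for interface parity with
    the pairwise path and not used here.

    With ``threshold=inf`` reporting is disabled and every database
    sequence is returned; sequences with no alignable region at all are
    assigned the null expectation E = N (the number of targets).
    """
    del calibration
    if not db:
        return []
    block = _digital_db(db)
    background = pyhmmer.plan7.Background(_AA_ALPHABET)
    if math.isinf(threshold):
        # reporting disabled: let every sequence through the filter cascade
        pipeline = pyhmmer.plan7.Pipeline(
            _AA_ALPHABET,
            background=background,
            E=1e30,
            F1=1.0,
            F2=1.0,
            F3=1.0,
            bias_filter=False,
        )
    else:
        pipeline = pyhmmer.plan7.Pipeline(
            _AA_ALPHABET, background=background, E=max(threshold, 1e-300)
        )
    top = pipeline.search_hmm(profile.hmm, block)
    hits = []
    for hit in top:
        ev = float(hit.evalue)
        name = hit.name if isinstance(hit.name, str) else hit.name.decode()
        if ev < threshold or math.isinf(threshold):
            hits.append(
                SearchHit(
                    target_gene_id=name,
                    family=profile.family,
                    score=float(hit.score),
                    evalue=max(ev, 1e-300),
                )
            )
    if math.isinf(threshold):
        scored = {h.target_gene_id for h in hits}
        for gene_id in sorted(db):
            if gene_id not in scored:
                hits.append(
                    SearchHit(
                        target_gene_id=gene_id,
                        family=profile.family,
                        score=0.0,
                        evalue=float(len(db)),
                    )
                )
    hits.sort(key=lambda h: (h.evalue, h.target_gene_id))
    return hits


def write_hits_tsv(hits: Iterable[SearchHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tfamily\tscore\tevalue\n")
        for h in hits:
            fh.write(f"{h.target_gene_id}\t{h.family}\t{h.score:.2f}\t{h.evalue:.3g}\n")


def shuffle_protein(seq: str, rng: np.random.Generator) -> str:
    """Residue shuffle preserving composition (decoy construction)."""
    return "".join(rng.permutation(list(seq)))
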