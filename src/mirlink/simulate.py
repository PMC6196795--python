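"""Synthetic paired miRNA/mRNA expression data with planted regulations.

The generator emulates a two-condition (drought vs. control) microarray
design at the scale of a deregulated-feature subset: a small miRNA matrix and
a larger mRNA matrix over the same replicated samples, a sequence-candidate
pair set, and a ground-truth record of the planted miRNA->mRNA regulations.

Model
-----
Every feature draws a baseline log2 intensity from Normal(8, 1).  miRNAs are
condition-responsive: each receives a +/- ``effect_size`` log2 shift in the
treated samples (sign drawn with probability ``up_fraction`` of being up,
mirroring the strong downregulation skew seen in drought-stressed rice).
A planted regulation makes the target mRNA a decreasing function of its
regulator: the target's profile is its baseline minus
``regulation_strength`` times the centred miRNA profile (averaged over
regulators when several share a target), plus Gaussian noise.  Regulated
mRNAs therefore inherit a condition response through their regulator; other
mRNAs are flat by default (``mrna_de_fraction`` adds independently shifted
mRNAs to emulate condition-responsive transcripts that are not
miRNA-driven).

Candidate pairs contain every planted edge plus uniform decoys at rate
``candidate_fpr`` among non-planted pairs, emulating sequence-prediction
false positives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .expression import ExpressionMatrix, TREATED, CONTROL
from .targets import (
    CandidatePairSet,
    DEFAULT_PENALTIES,
    PenaltyScheme,
    duplex_expectation,
)

#: Fraction of condition-responsive miRNAs that are upregulated (9 of 76
#: deregulated miRNAs in the drought study this scale emulates).
DEFAULT_UP_FRACTION = 9 / 76


class SimulationError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass(frozen=True)
class SimulationConfig:
    n_mirna: int = 30
    n_mrna: int = 329
    n_reps_per_condition: int = 3
    n_planted_edges: int = 50
    effect_size: float = 2.5
    regulation_strength: float = 0.9
    noise_sd: float = 0.3
    candidate_fpr: float = 0.02
    seed: int = 0
    up_fraction: float = DEFAULT_UP_FRACTION
    mrna_de_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_mirna", "n_mrna", "n_reps_per_condition", "n_planted_edges"):
            if getattr(self, name) < 1:
                raise SimulationError(f"{name} must be >= 1")
        if not 0.0 <= self.regulation_strength <= 1.0:
            raise SimulationError("regulation_strength must be in [0, 1]")
        if self.noise_sd <= 0:
            raise SimulationError("noise_sd must be > 0")
        if not 0.0 <= self.candidate_fpr < 1.0:
            raise SimulationError("candidate_fpr must be in [0, 1)")
        if not 0.0 <= self.up_fraction <= 1.0:
            raise SimulationError("up_fraction must be in [0, 1]")
        if not 0.0 <= self.mrna_de_fraction <= 1.0:
            raise SimulationError("mrna_de_fraction must be in [0, 1]")
        if self.n_planted_edges > self.n_mirna * self.n_mrna:
            raise SimulationError("n_planted_edges exceeds number of possible pairs")


@dataclass
class GroundTruth:
    """Planted regulations and true condition-responsive feature lists."""

    planted_edges: list[tuple[str, str, str]]  # (miRNA, mRNA, sign), sign="negative"
    de_mirnas: list[str]
    de_mrnas: list[str]

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {(m, g) for m, g, _ in self.planted_edges}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        raw["planted_edges"] = [tuple(e) for e in raw["planted_edges"]]
        return cls(**raw)


def _sample_ids(n_reps: int) -> tuple[list[str], np.ndarray]:
    names = [f"{CONTROL}_{i + 1}" for i in range(n_reps)] + [
        f"{TREATED}_{i + 1}" for i in range(n_reps)
    ]
    treated = np.r_[np.zeros(n_reps, dtype=bool), np.ones(n_reps, dtype=bool)]
    return names, treated


def generate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, CandidatePairSet, GroundTruth]:
    """Generate paired matrices, candidate pairs and ground truth.

    Deterministic: identical configs (including seed) give identical output.
    """
    rng = np.random.default_rng(config.seed)
    n_samples = 2 * config.n_reps_per_condition
    sample_names, treated = _sample_ids(config.n_reps_per_condition)
    mirna_ids = [f"miR-{i + 1:03d}" for i in range(config.n_mirna)]
    mrna_ids = [f"mRNA-{i + 1:04d}" for i in range(config.n_mrna)]

    # miRNA matrix: all features condition-responsive (the matrix emulates a
    # deregulated subset), mostly downregulated.
    mi_base = rng.normal(8.0, 1.0, config.n_mirna)
    mi_dir = np.where(rng.random(config.n_mirna) < config.up_fraction, 1.0, -1.0)
    mi = (
        mi_base[None, :]
        + treated[:, None] * (mi_dir * config.effect_size)[None, :]
        + rng.normal(0.0, config.noise_sd, (n_samples, config.n_mirna))
    )

    # mRNA matrix before regulation: baseline plus optional independent shifts.
    mr_base = rng.normal(8.0, 1.0, config.n_mrna)
    mr_dir = np.where(rng.random(config.n_mrna) < 0.5, 1.0, -1.0)
    mr_is_de = rng.random(config.n_mrna) < config.mrna_de_fraction
    mr = (
        mr_base[None, :]
        + treated[:, None] * (mr_dir * config.effect_size * mr_is_de)[None, :]
        + rng.normal(0.0, config.noise_sd, (n_samples, config.n_mrna))
    )

    # Plant edges: distinct (miRNA, mRNA) pairs; targets may share regulators.
    flat = rng.choice(
        config.n_mirna * config.n_mrna, size=config.n_planted_edges, replace=False
    )
    edge_src = flat // config.n_mrna
    edge_tgt = flat % config.n_mrna
    by_target: dict[int, list[int]] = {}
    for j, i in zip(edge_src, edge_tgt):
        by_target.setdefault(int(i), []).append(int(j))
    for i, regs in by_target.items():
        centred = mi[:, regs] - mi[:, regs].mean(axis=0)
        mr[:, i] = (
            rng.normal(8.0, 1.0)
            - config.regulation_strength * centred.mean(axis=1)
            + rng.normal(0.0, config.noise_sd, n_samples)
        )

    planted = [
        (mirna_ids[int(j)], mrna_ids[int(i)], "negative")
        for j, i in zip(edge_src, edge_tgt)
    ]
    planted_pairs = {(int(j), int(i)) for j, i in zip(edge_src, edge_tgt)}

    # Candidate set: planted edges plus uniform decoys.
    candidates = CandidatePairSet()
    decoy_mask = rng.random((config.n_mirna, config.n_mrna)) < config.candidate_fpr
    for j in range(config.n_mirna):
        for i in np.nonzero(decoy_mask[j])[0]:
            if (j, int(i)) not in planted_pairs:
                candidates.add(mirna_ids[j], mrna_ids[int(i)], "predictor1")
                candidates.add(mirna_ids[j], mrna_ids[int(i)], "predictor2")
    for mirna, mrna, _ in planted:
        candidates.add(mirna, mrna, "predictor1")
        candidates.add(mirna, mrna, "predictor2")

    de_mrnas = sorted(
        {mrna_ids[int(i)] for i in edge_tgt}
        | {mrna_ids[i] for i in np.nonzero(mr_is_de)[0]}
    )
    truth = GroundTruth(planted_edges=planted, de_mirnas=list(mirna_ids), de_mrnas=de_mrnas)

    conditions = pd.Series(
        [TREATED if t else CONTROL for t in treated], index=sample_names, name="condition"
    )
    mirna_matrix = ExpressionMatrix(
        pd.DataFrame(mi.T, index=mirna_ids, columns=sample_names), conditions
    )
    mrna_matrix = ExpressionMatrix(
        pd.DataFrame(mr.T, index=mrna_ids, columns=sample_names), conditions.copy()
    )
    return mirna_matrix, mrna_matrix, candidates, truth


# ---------------------------------------------------------------------------
# Duplex sequence generation
# ---------------------------------------------------------------------------

_EDIT_PLANS = (
    # (n_core_mismatch, n_core_wobble, n_tail_mismatch, n_tail_wobble)
    (0, 0, 0, 0),   # perfect site, expectation 0
    (1, 0, 0, 0),   # one core mismatch, expectation 2
    (0, 1, 0, 0),   # one core wobble, expectation 1
    (0, 0, 1, 0),   # one tail mismatch, expectation 1
    (0, 0, 0, 1),   # one tail wobble, expectation 0.5
    (0, 1, 0, 1),   # core wobble + tail wobble, expectation 1.5
)

_MISMATCH_CHOICES = {
    # miRNA base -> target bases that are neither complement nor wobble
    "A": ("A", "C", "G"),
    "C": ("C", "A", "U"),
    "G": ("G", "A"),
    "U": ("U", "C"),
}


def _revcomp_site(mirna_seq: str) -> list[str]:
    """Perfect target site (5'->3') for a miRNA, as a mutable base list."""
    return list(str(Seq(mirna_seq).reverse_complement_rna()))


def generate_duplex_sequences(
    n_sites: int,
    seed: int = 0,
    mirna_length: int = 21,
    transcript_length: int = 120,
    penalties: PenaltyScheme = DEFAULT_PENALTIES,
):
    """Generate miRNAs and transcripts with planted target sites.

    Each transcript carries one planted site derived from the matching
    miRNA's perfect reverse complement with a small number of mismatches
    and/or G:U wobbles (cycling through a fixed set of edit plans), so the
    intended expectation scores cover 0-2 under the default penalties.

    Returns ``(mirna_records, transcript_records, site_truth)`` where the
    records are Biopython ``SeqRecord`` lists and ``site_truth`` is a
    DataFrame with columns mirna_id, transcript_id, site_start, expectation.
    """
    if n_sites < 1:
        raise SimulationError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGU"))
    core = penalties.core_start, penalties.core_end
    mirna_records, transcript_records, rows = [], [], []
    for k in range(n_sites):
        mirna_id = f"sim-miR-{k + 1:03d}"
        transcript_id = f"sim-tx-{k + 1:03d}"
        mirna_seq = "".join(rng.choice(bases, mirna_length))
        site = _revcomp_site(mirna_seq)
        plan = _EDIT_PLANS[k % len(_EDIT_PLANS)]
        n_core_mm, n_core_wo, n_tail_mm, n_tail_wo = plan
        core_pos = [i for i in range(1, mirna_length + 1) if core[0] <= i <= core[1]]
        tail_pos = [i for i in range(1, mirna_length + 1) if i not in core_pos]

        def apply(positions, count, wobble):
            chosen = []
            pool = [
                p
                for p in positions
                if not wobble or mirna_seq[p - 1] in ("G", "U")
            ]
            rng.shuffle(pool)
            for p in pool[:count]:
                m = mirna_seq[p - 1]
                if wobble:
                    new = "U" if m == "G" else "G"
                else:
                    new = rng.choice(_MISMATCH_CHOICES[m])
                site[mirna_length - p] = new
                chosen.append(p)
            return len(chosen)

        apply(core_pos, n_core_mm, wobble=False)
        apply(core_pos, n_core_wo, wobble=True)
        apply(tail_pos, n_tail_mm, wobble=False)
        apply(tail_pos, n_tail_wo, wobble=True)

        site_seq = "".join(site)
        start = int(rng.integers(0, transcript_length - mirna_length + 1))
        flank = "".join(rng.choice(bases, transcript_length))
        transcript_seq = flank[:start] + site_seq + flank[start + mirna_length :]
        score = duplex_expectation(
            mirna_seq,
            site_seq,
            penalties,
            mirna_id=mirna_id,
            transcript_id=transcript_id,
            site_start=start,
        )
        mirna_records.append(SeqRecord(Seq(mirna_seq), id=mirna_id, description=""))
        transcript_records.append(
            SeqRecord(Seq(transcript_seq), id=transcript_id, description="")
        )
        rows.append(
            {
                "mirna_id": mirna_id,
                "transcript_id": transcript_id,
                "site_start": start,
                "expectation": score.expectation,
            }
        )
    site_truth = pd.DataFrame(rows)
    return mirna_records, transcript_records, site_truth


def write_fasta(records, path) -> None:
    SeqIO.write(records, str(path), "fasta")
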