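"""Seeded synthetic-data generators for every pipeline stage.

Each generator emulates the statistical structure its downstream consumer
assumes — planted kinase motifs inside annotated topology segments,
block-structured single-cell FPKM matrices with dropout, two-population
Fura-2 trace mixtures with a terminal KCl stimulus, and dose-dependent
lickometer counts — and returns a ground-truth table alongside the data so
tests can check recovery exactly.  Identical seeds give identical outputs.

Background sequence residues are drawn uniformly over the 20 canonical
amino acids, and any background position that would by chance complete a
consensus or T/SxxH match is mutated away, so planted-site accounting is
exact rather than probabilistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .caimaging import StimulusSchedule
from .seqscreen import (
    AMINO_ACIDS,
    MotifSite,
    ProteinRecord,
    TopologySegment,
    extract_peptide,
    scan_consensus,
    scan_txxh,
)

__all__ = [
    "MotifPlan",
    "gen_proteome",
    "trpa1_scaffold",
    "TRPA1_SCAFFOLD_SITES",
    "gen_sc_matrix",
    "gen_traces",
    "gen_lick_sessions",
    "write_fasta",
]

# residues safe to use at wildcard positions of a planted motif: no S/T/P/H
# so the planted window can never seed a second, unplanned match
_NEUTRAL = "ACDEFGILMNQVWY"


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# proteome generator


@dataclass
class MotifPlan:
    """Counts of planted acceptor sites by topology context and motif class."""

    cytoplasmic_consensus: int = 0
    transmembrane_consensus: int = 0
    extracellular_consensus: int = 0
    cytoplasmic_txxh: int = 0

    def total(self) -> int:
        return (
            self.cytoplasmic_consensus
            + self.transmembrane_consensus
            + self.extracellular_consensus
            + self.cytoplasmic_txxh
        )


def _random_sequence(rng: np.random.Generator, length: int) -> list[str]:
    return list(rng.choice(list(AMINO_ACIDS), size=length))


def _scrub(seq: list[str], protected: set[int]) -> None:
    """Mutate background acceptors so only planted motifs match.

    Any consensus or T/SxxH acceptor not in ``protected`` (1-based) is
    replaced by alanine; repeated until no unplanned match remains.
    Mutation only ever destroys matches, so this terminates.
    """
    while True:
        record = ProteinRecord("tmp", "".join(seq))
        extra = [
            s.acceptor_pos
            for s in scan_consensus(record) + scan_txxh(record)
            if s.acceptor_pos not in protected
        ]
        if not extra:
            return
        for pos in extra:
            seq[pos - 1] = "A"


def _plant_motif(
    seq: list[str], pos: int, motif_class: str, rng: np.random.Generator
) -> str:
    """Write a 4-mer motif with acceptor at 1-based ``pos``; returns window."""
    acceptor = rng.choice(["S", "T"])
    mid = rng.choice(list(_NEUTRAL))
    if motif_class == "consensus":
        window = acceptor + "P" + mid + rng.choice(["K", "R"])
    elif motif_class == "both":
        window = acceptor + "P" + mid + "H"
    elif motif_class == "txxh":
        window = acceptor + rng.choice(list(_NEUTRAL)) + mid + "H"
    else:
        raise ValueError(f"unknown motif class {motif_class!r}")
    seq[pos - 1 : pos + 3] = list(window)
    return window


def gen_proteome(
    n_proteins: int,
    plan: MotifPlan,
    protein_length: int = 300,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Random proteome with planted, topology-annotated motif sites.

    Sites are spread over proteins at acceptor positions spaced >= 15
    residues apart (and >= 4 from either end so the 10-mer assay window is
    never truncated); each planted site gets a topology segment of the
    requested kind spanning acceptor-5 .. acceptor+8.  Returns the records
    and a truth table with one row per planted site.
    """
    if plan.total() == 0:
        raise ValueError("empty motif plan")
    per_protein_capacity = (protein_length - 12) // 15
    if plan.total() > n_proteins * per_protein_capacity:
        raise ValueError("motif plan exceeds proteome capacity")
    rng = _rng(seed)

    jobs = (
        [("cytoplasmic", "consensus")] * plan.cytoplasmic_consensus
        + [("transmembrane", "consensus")] * plan.transmembrane_consensus
        + [("extracellular", "consensus")] * plan.extracellular_consensus
        + [("cytoplasmic", "txxh")] * plan.cytoplasmic_txxh
    )
    rng.shuffle(jobs)
    assignment: list[list[tuple[str, str]]] = [[] for _ in range(n_proteins)]
    for k, job in enumerate(jobs):
        assignment[k % n_proteins].append(job)

    records: list[ProteinRecord] = []
    truth_rows = []
    for idx in range(n_proteins):
        pid = f"syn{idx:04d}"
        seq = _random_sequence(rng, protein_length)
        placed: list[int] = []
        segs: list[TopologySegment] = []
        for kind, mclass in assignment[idx]:
            for _ in range(1000):
                pos = int(rng.integers(4, protein_length - 8))
                if all(abs(pos - q) >= 15 for q in placed):
                    break
            else:  # pragma: no cover - capacity pre-checked
                raise RuntimeError("could not place motif")
            placed.append(pos)
            window = _plant_motif(seq, pos, mclass, rng)
            segs.append(
                TopologySegment(kind, max(1, pos - 5), min(protein_length, pos + 8))
            )
            truth_rows.append(
                {
                    "protein_id": pid,
                    "acceptor_pos": pos,
                    "acceptor_res": window[0],
                    "motif_class": mclass,
                    "topology_kind": kind,
                    "window": window,
                }
            )
        _scrub(seq, set(placed))
        records.append(ProteinRecord(pid, "".join(seq), segs))

    truth = (
        pd.DataFrame(
            truth_rows,
            columns=[
                "protein_id",
                "acceptor_pos",
                "acceptor_res",
                "motif_class",
                "topology_kind",
                "window",
            ],
        )
        .sort_values(["protein_id", "acceptor_pos"])
        .reset_index(drop=True)
    )
    rec_by_id = {r.id: r for r in records}
    truth["peptide10"] = [
        extract_peptide(
            rec_by_id[row.protein_id],
            MotifSite(row.protein_id, row.acceptor_pos, row.acceptor_res, row.motif_class, row.window),
        ).sequence10
        for row in truth.itertuples(index=False)
    ]

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(records, out / "proteome.fasta")
        topo_rows = [
            {"protein_id": r.id, "kind": s.kind, "start": s.start, "end": s.end}
            for r in records
            for s in r.topology
        ]
        pd.DataFrame(topo_rows, columns=["protein_id", "kind", "start", "end"]).to_csv(
            out / "topology.tsv", sep="\t", index=False
        )
        truth.to_csv(out / "truth_sites.tsv", sep="\t", index=False)
    return records, truth


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    """Write records as wrapped FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# synthetic TRPA1 scaffold

#: Acceptor position -> planted 10-mer assay window (acceptor at window
#: position 4).  Five windows are the decapeptides used in the in vitro
#: kinase assay; the T485 window is one of them with its acceptor Ser
#: changed to Thr so every site keeps its published acceptor residue.
TRPA1_SCAFFOLD_SITES: dict[int, str] = {
    101: "YGNTPLHCAA",
    134: "HGMTPLHLAA",
    242: "NMMSPLHIAV",
    416: "DGCTPLHYAC",
    449: "DKKSPLHFAA",
    485: "KKATPLHLAV",
}

_SCAFFOLD_DECOYS = {650: "unknown", 800: "transmembrane"}


def trpa1_scaffold(seed: int = 1125) -> ProteinRecord:
    """SYNTHETIC stand-in for the mouse TRPA1 protein (not the real sequence).

    A 1125-residue random scaffold carrying the six ankyrin-repeat kinase
    consensus windows at their published acceptor positions (T101, T134,
    S242, T416, S449, T485) inside an annotated N-terminal cytoplasmic
    region (1-605), plus two decoy consensus sites outside it: one in an
    unannotated linker (650) and one in an annotated transmembrane segment
    (800).  Everything between the planted windows is random background
    scrubbed of accidental matches, so a consensus scan restricted to the
    cytoplasmic region finds exactly the six published sites.

    Use only for exercising the screen; for the real census download the
    translated GenBank record and run the same code path on it.
    """
    length = 1125
    rng = _rng(seed)
    seq = _random_sequence(rng, length)
    protected: set[int] = set()
    for acc, window10 in TRPA1_SCAFFOLD_SITES.items():
        seq[acc - 4 : acc + 6] = list(window10)
        protected.add(acc)
    for acc in _SCAFFOLD_DECOYS:
        _plant_motif(seq, acc, "consensus", rng)
        protected.add(acc)
    _scrub(seq, protected)
    topology = [
        TopologySegment("cytoplasmic", 1, 605),
        TopologySegment("transmembrane", 720, 975),
    ]
    return ProteinRecord("TRPA1_scaffold_synthetic", "".join(seq), topology)


# ---------------------------------------------------------------------------
# single-cell matrix generator


def gen_sc_matrix(
    blocks: Sequence[Mapping],
    genes: Sequence[str],
    dropout: float = 0.0,
    background_positivity: float = 0.05,
    threshold: float = 5.0,
    seed: int = 0,
    nested_pairs: Sequence[tuple[str, str]] = (),
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Block-structured single-cell FPKM matrix with planted positivity.

    ``blocks`` is a sequence of ``{"name": ..., "n_cells": ...,
    "positivity": {gene: fraction}}``; genes absent from a block's map use
    ``background_positivity``.  ``nested_pairs`` lists (sub, sup) gene
    pairs whose positive cells are forced to satisfy sub ⊆ sup, giving an
    exact 100% conditional coexpression fraction sub→sup.  Positive entries
    draw FPKM >= threshold, negative entries < threshold; ``dropout``
    zeroes positive entries independently, thinning measured prevalence by
    (1 - dropout).

    Returns the dense matrix and a truth table of planted and expected
    (post-dropout) prevalence per gene.
    """
    if not 0 <= dropout < 1:
        raise ValueError("dropout must be in [0, 1)")
    rng = _rng(seed)
    sub_of = dict(nested_pairs)
    n_total = sum(b["n_cells"] for b in blocks)
    cells = [f"cell{i:05d}" for i in range(n_total)]
    masks = {g: np.zeros(n_total, dtype=bool) for g in genes}

    start = 0
    planted: dict[str, float] = {g: 0.0 for g in genes}
    for block in blocks:
        stop = start + block["n_cells"]
        pos = block.get("positivity", {})

        def frac_for(g: str) -> float:
            return float(pos.get(g, background_positivity))

        # supersets (and plain genes) first, then nested subsets
        plain = [g for g in genes if g not in sub_of]
        for g in plain:
            p = frac_for(g)
            masks[g][start:stop] = rng.random(block["n_cells"]) < p
            planted[g] += p * block["n_cells"]
        for g, sup in sub_of.items():
            p, p_sup = frac_for(g), frac_for(sup)
            if p > p_sup:
                raise ValueError(f"nested pair {g}⊆{sup}: {p} > {p_sup}")
            keep = rng.random(block["n_cells"]) < (p / p_sup if p_sup else 0.0)
            masks[g][start:stop] = masks[sup][start:stop] & keep
            planted[g] += p * block["n_cells"]
        start = stop

    values = np.empty((len(genes), n_total))
    for i, g in enumerate(genes):
        m = masks[g].copy()
        if dropout:
            m &= rng.random(n_total) >= dropout
        n_pos = int(m.sum())
        row = rng.uniform(0.0, threshold * 0.8, size=n_total)
        row[m] = threshold * (1.0 + rng.exponential(1.0, size=n_pos))
        values[i] = row
    matrix = pd.DataFrame(values, index=list(genes), columns=cells)

    truth = pd.DataFrame(
        {
            "gene": list(genes),
            "planted_prevalence_pct": [100.0 * planted[g] / n_total for g in genes],
            "expected_prevalence_pct": [
                100.0 * planted[g] / n_total * (1.0 - dropout) for g in genes
            ],
        }
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        long = matrix.stack()
        trip = long[long > 0].reset_index()
        trip.columns = ["gene", "cell", "fpkm"]
        trip.to_csv(out / "matrix_triplets.tsv", sep="\t", index=False)
        truth.to_csv(out / "truth_prevalence.tsv", sep="\t", index=False)
    return matrix, truth


# ---------------------------------------------------------------------------
# Fura-2 trace generator


def _transient(
    time: np.ndarray,
    onset: float,
    offset: float,
    tau_rise: float,
    tau_decay: float,
) -> np.ndarray:
    """Unit-peak rise/decay transient on the sampled time grid."""
    shape = np.zeros_like(time)
    rising = (time >= onset) & (time <= offset)
    shape[rising] = 1.0 - np.exp(-(time[rising] - onset) / tau_rise)
    after = time > offset
    level = 1.0 - np.exp(-(offset - onset) / tau_rise)
    shape[after] = level * np.exp(-(time[after] - offset) / tau_decay)
    peak = shape.max()
    return shape / peak if peak > 0 else shape


def gen_traces(
    n_mice: int = 7,
    neurons_per_mouse: int | tuple[float, float] = (31.0, 7.0),
    responder_fraction: float = 0.4,
    responder_fold: tuple[float, float] = (1.45, 0.10),
    nonresponder_peak: tuple[float, float] = (1.00, 0.05),
    desensitize_prob: float = 0.0,
    kcl_responder_fraction: float = 0.95,
    kcl_fold: tuple[float, float] = (1.9, 0.2),
    schedule: StimulusSchedule | None = None,
    sample_interval: float = 2.0,
    noise_sd: float = 0.005,
    tau_rise: float = 5.0,
    tau_decay: float = 20.0,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-population Fura-2 relative-ratio traces with a terminal KCl pulse.

    Each mouse contributes ``neurons_per_mouse`` neurons (an int, or a
    (mean, sd) normal draw rounded to >= 1, default matching ~31 +/- 7 per
    animal).  Excitable neurons (fraction ``kcl_responder_fraction``) carry
    a KCl transient; among them a ``responder_fraction`` respond to the
    agonist with peak fold ~ N(responder_fold), the rest have peak folds ~
    N(nonresponder_peak) whose sub-baseline half shows up as a flat trace.
    Responders desensitize with probability ``desensitize_prob``: their
    low-dose transient never decays and they skip the high dose.

    Returns a long-format traces table (neuron_id, mouse_id, time, ratio)
    and a per-neuron truth table.
    """
    if schedule is None:
        schedule = StimulusSchedule.default()
    rng = _rng(seed)
    t_end = schedule.kcl.washout_end
    time = np.arange(0.0, t_end + sample_interval, sample_interval)
    low, high = schedule.agonist_applications[0], None
    if len(schedule.agonist_applications) > 1:
        high = schedule.agonist_applications[1]
    kcl = schedule.kcl

    shape_fast = {
        app.label: _transient(time, app.onset, app.offset, tau_rise, tau_decay)
        for app in schedule.applications
    }
    shape_stuck = _transient(time, low.onset, low.offset, tau_rise, 1e9)

    frames = []
    truth_rows = []
    for m in range(n_mice):
        mouse = f"mouse{m:02d}"
        if isinstance(neurons_per_mouse, tuple):
            n_neurons = max(1, int(round(rng.normal(*neurons_per_mouse))))
        else:
            n_neurons = int(neurons_per_mouse)
        for j in range(n_neurons):
            neuron = f"{mouse}_n{j:03d}"
            excitable = bool(rng.random() < kcl_responder_fraction)
            responder = bool(excitable and rng.random() < responder_fraction)
            desens = bool(responder and rng.random() < desensitize_prob)
            trace = np.ones_like(time)
            low_peak = np.nan
            high_peak = np.nan
            kcl_peak = np.nan
            if responder:
                low_peak = rng.normal(*responder_fold)
                trace = trace + (low_peak - 1.0) * (
                    shape_stuck if desens else shape_fast[low.label]
                )
                if high is not None and not desens:
                    high_peak = rng.normal(*responder_fold)
                    trace = trace + (high_peak - 1.0) * shape_fast[high.label]
            else:
                low_peak = rng.normal(*nonresponder_peak)
                if low_peak > 1.0:
                    trace = trace + (low_peak - 1.0) * shape_fast[low.label]
            if excitable:
                kcl_peak = rng.normal(*kcl_fold)
                trace = trace + (kcl_peak - 1.0) * shape_fast[kcl.label]
            trace = trace + rng.normal(0.0, noise_sd, size=time.size)
            frames.append(
                pd.DataFrame(
                    {
                        "neuron_id": neuron,
                        "mouse_id": mouse,
                        "time": time,
                        "ratio": trace,
                    }
                )
            )
            truth_rows.append(
                {
                    "neuron_id": neuron,
                    "mouse_id": mouse,
                    "excitable": excitable,
                    "responder": responder,
                    "desensitized": desens,
                    "low_peak": low_peak,
                    "high_peak": high_peak,
                    "kcl_peak": kcl_peak,
                }
            )
    traces = pd.concat(frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        traces.to_csv(out / "traces.csv", index=False)
        truth.to_csv(out / "truth_neurons.csv", index=False)
        sched_rows = [
            {
                "label": a.label,
                "onset": a.onset,
                "offset": a.offset,
                "washout_end": a.washout_end,
            }
            for a in schedule.applications
        ]
        pd.DataFrame(sched_rows).to_csv(out / "schedule.csv", index=False)
    return traces, truth


# ---------------------------------------------------------------------------
# lickometer generator


def gen_lick_sessions(
    genotype_effects: Mapping[str, Mapping[float, float]],
    n_animals_per_genotype: int = 4,
    n_sessions: int = 5,
    baseline_mean_licks: float = 1000.0,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lick counts with planted dose-dependent aversion.

    ``genotype_effects`` maps genotype -> {concentration_uM: expected
    percent-of-baseline licking}.  Water (baseline) and agonist sessions
    draw counts from Poisson distributions with the matching means, so the
    recovered percent-of-baseline is unbiased around the planted value.
    """
    rng = _rng(seed)
    rows = []
    truth_rows = []
    for geno in sorted(genotype_effects):
        effects = genotype_effects[geno]
        for conc in sorted(effects):
            truth_rows.append(
                {
                    "genotype": geno,
                    "concentration_uM": float(conc),
                    "planted_pct_baseline": float(effects[conc]),
                }
            )
        for a in range(n_animals_per_genotype):
            animal = f"{geno}_a{a:02d}"
            for s in range(n_sessions):
                rows.append(
                    {
                        "animal_id": animal,
                        "genotype": geno,
                        "condition": "water",
                        "session": s,
                        "licks": int(rng.poisson(baseline_mean_licks)),
                    }
                )
            for conc in sorted(effects):
                mean = baseline_mean_licks * effects[conc] / 100.0
                for s in range(n_sessions):
                    rows.append(
                        {
                            "animal_id": animal,
                            "genotype": geno,
                            "condition": float(conc),
                            "session": s,
                            "licks": int(rng.poisson(mean)),
                        }
                    )
    sessions = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sessions.to_csv(out / "sessions.csv", index=False)
        truth.to_csv(out / "truth_licks.csv", index=False)
    return sessions, truth
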