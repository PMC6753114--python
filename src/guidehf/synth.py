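"""Synthetic fixtures with known ground truth.

Two generators mirror the two halves of the pipeline:

* :func:`simulate_activity_dataset` draws spacers and produces activities from
  a planted sequence/biofeature rule through a logistic link plus Gaussian
  noise on the logit — the regression models are judged on recovering it.
* :func:`make_simulated_screen` / :func:`simulate_screen_reads` emit plasmid
  and edited FASTQ libraries for a synthetic guide manifest, with planted
  per-guide indel frequencies, synthesis/PCR error sequences injected into
  both libraries, indels placed at the canonical cut site (between
  protospacer positions 17 and 18, 3 bp 5' of the PAM) and a two-level
  (Q40/Q5) quality model that exercises the quality-masking path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .features.registry import MINIMAL_REGISTRY, assemble_biofeatures
from .sequences import (
    SGRNA_SCAFFOLD,
    GuideRecord,
    LibraryManifest,
    write_fastq,
)

__all__ = [
    "PlantedRule",
    "default_rule",
    "tm_rule",
    "simulate_activity_dataset",
    "SimulatedScreen",
    "make_simulated_screen",
    "simulate_screen_reads",
]

_NT = np.array(list("ACGT"))
_NT_IDX = {nt: i for i, nt in enumerate("ACGT")}

# Centering/scale applied to biofeatures inside planted rules, so coefficients
# are on comparable O(1) scales.
_BIOFEATURE_SCALES = {
    "tm_global": (55.0, 10.0),
    "gc_fraction": (0.5, 0.25),
    "gc_count": (10.0, 5.0),
    "self_fold_score": (-2.0, 2.0),
}


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class PlantedRule:
    """Ground-truth activity rule: logit-linear in position-nucleotide
    indicators, 4-mer motifs and (scaled) biofeatures, squashed by a logistic
    link; observation noise is Gaussian on the logit."""

    position_weights: np.ndarray  # (20, 4) over A,C,G,T
    motif_penalties: Mapping[str, float] = field(default_factory=dict)
    biofeature_coefs: Mapping[str, float] = field(default_factory=dict)
    intercept: float = 0.0
    noise_sd: float = 0.25
    motif_plant_rate: float = 0.15

    def logit_score(self, spacer: str) -> float:
        """Noiseless score on the logit scale."""
        s = self.intercept
        for pos, nt in enumerate(spacer):
            s += self.position_weights[pos, _NT_IDX[nt]]
        for motif, delta in self.motif_penalties.items():
            if motif in spacer:
                s += delta
        if self.biofeature_coefs:
            bio = assemble_biofeatures(spacer, registry=MINIMAL_REGISTRY)
            lookup = dict(zip(bio.names, bio.values))
            for name, coef in self.biofeature_coefs.items():
                center, scale = _BIOFEATURE_SCALES.get(name, (0.0, 1.0))
                s += coef * (lookup[name] - center) / scale
        return float(s)


def default_rule(noise_sd: float = 0.25) -> PlantedRule:
    """The standard study rule: a strong G at position 20, a mild C-20
    penalty, T disfavored PAM-proximally, a TTTT motif penalty and a
    melting-temperature effect."""
    w = np.zeros((20, 4))
    w[19, _NT_IDX["G"]] = 0.9
    w[19, _NT_IDX["C"]] = -0.4
    for pos in range(14, 20):
        w[pos, _NT_IDX["T"]] = -0.15
    return PlantedRule(
        position_weights=w,
        motif_penalties={"TTTT": -1.2},
        biofeature_coefs={"tm_global": 0.6},
        noise_sd=noise_sd,
    )


def tm_rule(noise_sd: float = 0.25) -> PlantedRule:
    """Variant rule dominated by the melting-temperature biofeature; used to
    measure the value of feeding hand-crafted features to the network."""
    w = np.zeros((20, 4))
    w[19, _NT_IDX["G"]] = 0.2
    return PlantedRule(
        position_weights=w,
        biofeature_coefs={"tm_global": 1.4},
        noise_sd=noise_sd,
    )


def _draw_spacers(n: int, rng: np.random.Generator, motifs: Sequence[str], rate: float) -> list[str]:
    first = rng.choice(list("AG"), size=n)
    rest = rng.choice(_NT, size=(n, 19))
    spacers = [f + "".join(r) for f, r in zip(first, rest)]
    # Plant motifs deliberately in a labeled fraction so motif effects are
    # identifiable even when they rarely occur by chance.
    for m in motifs:
        hit = rng.random(n) < rate
        for i in np.flatnonzero(hit):
            start = int(rng.integers(1, 20 - len(m) + 1))
            s = spacers[i]
            spacers[i] = s[:start] + m + s[start + len(m) :]
    return spacers


def simulate_activity_dataset(
    n: int, rule: PlantedRule | None = None, seed: int = 0
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Spacers, noisy activities in [0,1], and noiseless true activities."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rule = rule or default_rule()
    rng = np.random.default_rng(seed)
    spacers = _draw_spacers(
        n, rng, list(rule.motif_penalties), rule.motif_plant_rate
    )
    logits = np.array([rule.logit_score(s) for s in spacers])
    true_scores = _logistic(logits)
    noisy = _logistic(logits + rng.normal(0.0, rule.noise_sd, size=n))
    return spacers, np.clip(noisy, 0.0, 1.0), true_scores


# --------------------------------------------------------------------------
# Screen read simulation


@dataclass
class SimulatedScreen:
    """A synthetic pooled screen: manifest, planted truth and read model."""

    manifest: LibraryManifest
    true_frequency: dict[str, float]
    error_sequences: dict[str, list[str]]  # per-guide synthesis/PCR variants
    depth: int = 5_000
    error_rate: float = 0.1  # total probability a read is an error variant
    low_quality_read_rate: float = 0.05  # reads carrying one Q5 base
    seed: int = 0


def _random_context(spacer: str, rng: np.random.Generator) -> str:
    flank5 = "".join(rng.choice(_NT, size=5))
    flank3 = "".join(rng.choice(_NT, size=5))
    pam = rng.choice(_NT) + "GG"
    return flank5 + spacer + pam + flank3


def make_simulated_screen(
    n_guides: int = 200,
    depth: int = 5_000,
    error_rate: float = 0.1,
    seed: int = 0,
    n_error_variants: int = 2,
    low_quality_read_rate: float = 0.05,
) -> SimulatedScreen:
    """Build a synthetic manifest with planted frequencies and error variants.

    True frequencies are Beta(2,2) distributed; each guide carries
    ``n_error_variants`` substitution variants of its target (same length as
    the design, hence never confusable with an indel allele).
    """
    rng = np.random.default_rng(seed)
    records: list[GuideRecord] = []
    seen: set[str] = set()
    while len(records) < n_guides:
        spacer = str(rng.choice(list("AG"))) + "".join(rng.choice(_NT, size=19))
        if spacer in seen:
            continue
        seen.add(spacer)
        gid = f"g{len(records):05d}"
        records.append(
            GuideRecord(gid, f"gene{len(records)}", spacer, _random_context(spacer, rng))
        )
    manifest = LibraryManifest(records)
    true_freq = {r.guide_id: float(rng.beta(2, 2)) for r in records}
    error_seqs: dict[str, list[str]] = {}
    for rec in records:
        variants: set[str] = set()
        ctx = rec.target_context
        while len(variants) < n_error_variants:
            pos = int(rng.integers(0, len(ctx)))
            sub = str(rng.choice([b for b in "ACGT" if b != ctx[pos]]))
            var = ctx[:pos] + sub + ctx[pos + 1 :]
            if var != ctx:
                variants.add(var)
        error_seqs[rec.guide_id] = sorted(variants)
    return SimulatedScreen(
        manifest,
        true_freq,
        error_seqs,
        depth=depth,
        error_rate=error_rate,
        low_quality_read_rate=low_quality_read_rate,
        seed=seed,
    )


def _indel_alleles(rec: GuideRecord, rng: np.random.Generator, k: int = 6) -> list[str]:
    """Distinct indel-bearing targets, cut 3 bp 5' of the PAM."""
    ctx = rec.target_context
    cut = rec.spacer_offset + 17
    alleles: set[str] = set()
    while len(alleles) < k:
        size = int(rng.integers(1, 11))
        if rng.random() < 0.5 and cut + size <= len(ctx):
            allele = ctx[:cut] + ctx[cut + size :]
        else:
            ins = "".join(rng.choice(_NT, size=size))
            allele = ctx[:cut] + ins + ctx[cut:]
        if allele != ctx:
            alleles.add(allele)
    return sorted(alleles)


def simulate_screen_reads(
    sim: SimulatedScreen, out_dir: str | Path
) -> tuple[Path, Path]:
    """Emit plasmid and edited FASTQ libraries; returns the two paths.

    Every read is barcode (spacer) + scaffold + target. Error variants are
    injected at the same planted rates into both libraries; edited reads are
    a Bernoulli(true frequency) draw among pre-built indel alleles.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(sim.seed)
    scaffold = sim.manifest.scaffold
    plasmid_path = out_dir / "plasmid.fastq"
    edited_path = out_dir / "edited.fastq"

    def _emit(library: str):
        for rec in sim.manifest:
            prefix = rec.spacer + scaffold
            design = rec.target_context
            variants = sim.error_sequences[rec.guide_id]
            per_variant = sim.error_rate / max(len(variants), 1)
            choices = variants + [None]  # None = not an error read
            probs = [per_variant] * len(variants) + [1.0 - sim.error_rate]
            picks = rng.choice(len(choices), size=sim.depth, p=probs)
            if library == "edited":
                alleles = _indel_alleles(rec, rng)
                edited_mask = rng.random(sim.depth) < sim.true_frequency[rec.guide_id]
                allele_pick = rng.integers(0, len(alleles), size=sim.depth)
            lowq = rng.random(sim.depth) < sim.low_quality_read_rate
            for i in range(sim.depth):
                pick = picks[i]
                if pick < len(variants):
                    target = variants[pick]
                elif library == "edited" and edited_mask[i]:
                    target = alleles[allele_pick[i]]
                else:
                    target = design
                seq = prefix + target
                qual = "I" * len(seq)
                if lowq[i]:
                    pos = int(rng.integers(0, len(seq)))
                    qual = qual[:pos] + "&" + qual[pos + 1 :]  # Q5
                yield f"{rec.guide_id}:{library}:{i}", seq, qual

    write_fastq(_emit("plasmid"), plasmid_path)
    write_fastq(_emit("edited"), edited_path)
    return plasmid_path, edited_path
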