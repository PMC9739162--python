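"""Synthetic-study generator with a planted ground truth.

Emulates the statistical structure of a case/control spinal-cord cohort
(three tissue regions, about 2.6 ALS samples per control) so that the whole
consensus -> differential expression -> seed scanning -> network ->
enrichment chain can run and be verified without any external data:

* two circRNA caller tables (CIRI2-style and CIRCexplorer2-style dialects)
  with a controlled number of shared junctions and independent per-caller
  read-count jitter;
* negative-binomial count matrices (circRNA and gene level) with planted
  per-tissue log2 fold changes and optional covariate effects on the
  log-mean;
* circRNA sequences whose background is seed-free for the whole miRNA panel
  (so planted sites are recovered with precision = recall = 1) with
  miRNA binding sites planted at known positions, some wrapping the
  back-spliced junction;
* a miRNA->gene target table linking the planted "sponge" miRNAs to a set
  of upregulated DE genes;
* a gene-set collection (GMT) containing one term enriched for those genes.

Seed-free background by construction: every panel miRNA seed (nucleotides
2-7) contains the dinucleotide GG, hence every target hexamer contains CC,
and background sequence is drawn from a first-order chain that never emits
C after C.  Planted motifs are inserted verbatim; each sequence is then
verified by scanning against the full panel and re-drawn in the rare case
an insertion boundary creates a spurious match.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as cio
from .diffexp import CountMatrix
from .junction import BackspliceJunction, CircRecord
from .sponge import MiRNA, SeedSite, TargetRecord, revcomp_rna, scan_sites

__all__ = [
    "SimConfig",
    "TruthManifest",
    "StudyBundle",
    "generate_study",
    "plant_seed_sites",
    "simulate_counts",
    "nb_counts",
]

_SITE_CYCLE = ("8mer", "7mer-m8", "7mer-A1", "6mer")
_SPAN = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults emulate the three-region spinal-cord cohort (sample sizes
    18/7, 16/6, 16/6 for cervical, thoracic and lumbar) at a desk-scale
    feature count.
    """

    n_tissues: int = 3
    samples_per_group: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"SCC": (18, 7), "SCT": (16, 6), "SCL": (16, 6)}
    )
    n_circ: int = 300
    n_genes: int = 2000
    n_mirnas: int = 150
    frac_de_circ: float = 0.2
    frac_de_genes: float = 0.1
    lfc_magnitude: float = 2.0
    nb_dispersion: float = 0.1
    mean_log_expression: float = 5.0
    caller_overlap: float = 0.8
    planted_sites_per_circ: int = 1
    seed: int = 0
    # secondary knobs
    frac_up: float = 0.7
    n_sponge_mirnas: int = 12
    n_affected_genes: int = 30
    circ_length: int = 400
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"RIN": 0.0, "PMI": 0.0, "sex": 0.0}
    )
    baseline_log_sd: float = 1.5

    def validate(self) -> None:
        bad: list[str] = []
        for name in ("frac_de_circ", "frac_de_genes", "caller_overlap", "frac_up"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                bad.append(f"{name}={v} not in [0,1]")
        if self.nb_dispersion <= 0:
            bad.append(f"nb_dispersion={self.nb_dispersion} must be > 0")
        for name in ("n_tissues", "n_circ", "n_genes", "n_mirnas"):
            if getattr(self, name) < 1:
                bad.append(f"{name}={getattr(self, name)} must be >= 1")
        if self.planted_sites_per_circ < 0:
            bad.append("planted_sites_per_circ must be >= 0")
        if len(self.samples_per_group) != self.n_tissues:
            bad.append(
                f"samples_per_group has {len(self.samples_per_group)} tissues, "
                f"n_tissues={self.n_tissues}"
            )
        for t, (nc, nk) in self.samples_per_group.items():
            if nc < 1 or nk < 1:
                bad.append(f"tissue {t}: group sizes must be >= 1")
        shared = round(self.caller_overlap * self.n_circ)
        if round(self.frac_de_circ * self.n_circ) > shared:
            bad.append(
                "frac_de_circ * n_circ exceeds the caller-shared junction count "
                f"({round(self.frac_de_circ * self.n_circ)} > {shared})"
            )
        for c, v in self.covariate_effects.items():
            if not 0.0 <= v < 1.0:
                bad.append(f"covariate_effects[{c}]={v} not in [0,1)")
        if bad:
            raise ValueError("invalid SimConfig: " + "; ".join(bad))


@dataclass
class TruthManifest:
    """Planted ground truth indexed by generated feature IDs."""

    de_circ_up: dict[str, list[str]]
    de_circ_down: dict[str, list[str]]
    de_genes_up: dict[str, list[str]]
    de_genes_down: dict[str, list[str]]
    planted_sites: list[tuple[str, str, int, str]]  # (circ, mirna, start, type)
    enriched_term: str
    covariate_effects: dict[str, float]
    sponge_mirnas: list[str]
    affected_genes: list[str]
    scanned_tissues: list[str]
    consensus_circ_ids: list[str]
    caller_shared: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        d["planted_sites"] = [tuple(s) for s in d["planted_sites"]]
        return cls(**d)


@dataclass
class StudyBundle:
    """Paths of all generated study files plus the in-memory truth."""

    outdir: Path
    caller_table_a: Path
    caller_table_b: Path
    circ_fasta: Path
    mirna_fasta: Path
    circ_counts: Path
    gene_counts: Path
    metadata: Path
    target_table: Path
    gmt: Path
    truth_json: Path
    truth: TruthManifest


# ---------------------------------------------------------------------------
# sequence machinery


def _random_cc_free(length: int, rng: np.random.Generator) -> str:
    """Random RNA with no CC dinucleotide (circularly): first-order chain."""
    alphabet = np.array(list("ACGU"))
    no_c = np.array(list("AGU"))
    out = []
    prev = ""
    for _ in range(length):
        pool = no_c if prev == "C" else alphabet
        prev = str(rng.choice(pool))
        out.append(prev)
    # closing the circle: the junction must not create CC either
    if out and out[-1] == "C" and out[0] == "C":
        out[0] = "A"
    return "".join(out)


def _site_motif(mirna: MiRNA, site_type: str) -> str:
    hexamer = revcomp_rna(mirna.seed6)
    if site_type == "6mer":
        return hexamer
    if site_type == "7mer-A1":
        return hexamer + "A"
    if mirna.nt8 is None:
        raise ValueError(f"{site_type} site requires a miRNA of length >= 8")
    m8 = revcomp_rna(mirna.nt8)
    if site_type == "7mer-m8":
        return m8 + hexamer
    if site_type == "8mer":
        return m8 + hexamer + "A"
    raise ValueError(f"unknown site type {site_type!r}")


def plant_seed_sites(
    sequence: str,
    mirna: MiRNA,
    positions: Sequence[int],
    site_types: Sequence[str],
) -> str:
    """Write exact target-site motifs into ``sequence`` (length unchanged).

    ``positions`` are 1-based starts of the full site span on the circular
    sequence; spans may wrap past the end.  The two flanking bases are
    adjusted where needed so that the planted class is exactly what a
    scanner recovers (e.g. a 7mer-m8 is not accidentally followed by an A,
    which would promote it to 8mer).  Overlapping planted sites (including
    their classifying flanks) raise an error: the truth would be ambiguous.
    """
    if len(positions) != len(site_types):
        raise ValueError("positions and site_types must have equal length")
    length = len(sequence)
    seq = list(sequence)
    occupied: set[int] = set()

    m8 = revcomp_rna(mirna.nt8) if mirna.nt8 is not None else None

    for pos, st in zip(positions, site_types):
        if not 1 <= pos <= length:
            raise ValueError(f"position {pos} outside sequence of length {length}")
        motif = _site_motif(mirna, st)
        span = len(motif)
        # reserve the span plus both classifying flanks
        cells = [(pos - 1 + k) % length for k in range(-1, span + 1)]
        if occupied & set(cells):
            raise ValueError(f"overlapping planted sites at position {pos}")
        occupied |= set(cells)
        for k, ch in enumerate(motif):
            seq[(pos - 1 + k) % length] = ch
        # flank cleanup: prevent unintended promotion to a stronger class
        pre_i = (pos - 2) % length
        post_i = (pos - 1 + span) % length
        if st in ("6mer", "7mer-A1") and m8 is not None and seq[pre_i] == m8:
            seq[pre_i] = "G" if m8 != "G" else "A"
        if st in ("6mer", "7mer-m8") and seq[post_i] == "A":
            seq[post_i] = "G"
    return "".join(seq)


# ---------------------------------------------------------------------------
# counts


def _assemble_sequence(
    length: int,
    placements: Sequence[tuple[MiRNA, int, str]],
    panel: Sequence[MiRNA],
    rng: np.random.Generator,
    max_rounds: int = 300,
) -> str:
    """Background + planted sites, repaired until exactly the planted sites
    are recoverable by scanning.

    Spurious seed matches can straddle a planted-motif boundary (part motif,
    part background); each repair round scans the sequence against the full
    panel and flips one background (non-motif-span) base inside every
    spurious hexamer window, respecting the flank constraints that keep the
    planted site classes exact, until the observed site set equals the
    planted truth.
    """
    seq = _random_cc_free(length, rng)
    for m, pos, st in placements:
        seq = plant_seed_sites(seq, m, [pos], [st])

    span_cells: set[int] = set()
    forbidden: dict[int, set[str]] = {}
    for m, pos, st in placements:
        span = _SPAN[st]
        span_cells.update((pos - 1 + k) % length for k in range(span))
        m8 = revcomp_rna(m.nt8) if m.nt8 is not None else None
        if st in ("6mer", "7mer-A1") and m8 is not None:
            forbidden.setdefault((pos - 2) % length, set()).add(m8)
        if st in ("6mer", "7mer-m8"):
            forbidden.setdefault((pos - 1 + span) % length, set()).add("A")
    expected = {(m.id, pos, st) for m, pos, st in placements}

    for rnd in range(max_rounds):
        found = [s for m in panel for s in scan_sites(seq, m, circular=True)]
        observed = {(s.mirna_id, s.start, s.site_type) for s in found}
        if observed == expected:
            return seq
        if expected - observed:
            raise RuntimeError(
                f"planted sites destroyed during repair: {sorted(expected - observed)}"
            )
        chars = list(seq)
        for s in found:
            key = (s.mirna_id, s.start, s.site_type)
            if key in expected:
                continue
            hex0 = (s.start - 1) % length
            if s.site_type in ("8mer", "7mer-m8"):  # reported start is the m8 cell
                hex0 = s.start % length
            window = [(hex0 + k) % length for k in range(6)]
            if rnd % 10 == 9:
                # stuck in a local repair cycle: re-randomize the whole
                # neighborhood of the stubborn window
                for cell in ((hex0 + k) % length for k in range(-3, 9)):
                    if cell in span_cells:
                        continue
                    opts = [
                        ch for ch in "AGU" if ch not in forbidden.get(cell, ())
                    ]
                    chars[cell] = opts[int(rng.integers(len(opts)))]
                continue
            # random cell/char choice avoids deterministic repair cycles
            free = [c for c in window if c not in span_cells]
            done = False
            for prefer_non_c in (True, False):
                for cell in (free[i] for i in rng.permutation(len(free))):
                    left, right = chars[(cell - 1) % length], chars[(cell + 1) % length]
                    options = [
                        ch for ch in "ACGU"
                        if ch != chars[cell]
                        and ch not in forbidden.get(cell, ())
                        and not (prefer_non_c and ch == "C" and "C" in (left, right))
                    ]
                    if options:
                        chars[cell] = options[int(rng.integers(len(options)))]
                        done = True
                        break
                if done:
                    break
            if not done:
                raise RuntimeError("no repairable cell in a spurious site window")
        seq = "".join(chars)
    raise RuntimeError("sequence repair did not converge")


def nb_counts(
    mean: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Negative-binomial draws with E=mean, Var=mean + dispersion*mean^2."""
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    mean = np.asarray(mean, dtype=float)
    if dispersion < 1e-8:  # Poisson limit
        return rng.poisson(mean).astype(float)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p).astype(float)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def simulate_counts(
    metadata: pd.DataFrame,
    feature_ids: Sequence[str],
    log2_baseline: np.ndarray,
    lfc_by_tissue: Mapping[str, Mapping[str, float]],
    dispersion: float,
    rng: np.random.Generator,
    covariate_effects: Mapping[str, float] | None = None,
    mean_log_expression: float = 5.0,
) -> CountMatrix:
    """Draw an NB count matrix for the given design.

    ``lfc_by_tissue[tissue][feature]`` is the planted log2 fold change
    (case vs control) of a DE feature in that tissue; absent features have
    condition-independent means.  ``covariate_effects`` maps RIN/PMI/sex
    (and optionally group) to target fractions of the per-feature
    log-expression variance; effects enter as linear terms on the log2
    mean with coefficients scaled against the approximate NB log-variance.
    """
    if metadata.empty:
        raise ValueError("empty design")
    for tissue, sub in metadata.groupby("tissue"):
        for cond in ("ALS", "control"):
            if (sub["condition"] == cond).sum() == 0:
                raise ValueError(f"tissue {tissue}: empty {cond} group")
    n_feat, n_samp = len(feature_ids), len(metadata)
    log2_baseline = np.asarray(log2_baseline, dtype=float)
    offsets = np.zeros((n_feat, n_samp))

    is_case = (metadata["condition"] == "ALS").to_numpy()
    fidx = {f: i for i, f in enumerate(feature_ids)}
    for tissue, lfcs in lfc_by_tissue.items():
        in_tissue = (metadata["tissue"] == tissue).to_numpy()
        cols = in_tissue & is_case
        for feat, lfc in lfcs.items():
            if feat in fidx:
                offsets[fidx[feat], cols] += lfc

    if covariate_effects and any(v > 0 for v in covariate_effects.values()):
        # approximate log2-scale NB variance at the typical expression level
        mu_typ = 2.0**mean_log_expression
        ln2sq = math.log(2.0) ** 2
        base_var = (1.0 / mu_typ + dispersion) / ln2sq
        total_frac = sum(covariate_effects.values())
        if total_frac >= 1.0:
            raise ValueError("covariate variance fractions must sum to < 1")
        z = {
            "RIN": _standardize(metadata["RIN"].to_numpy(float)),
            "PMI": _standardize(metadata["PMI"].to_numpy(float)),
            "sex": _standardize((metadata["sex"] == "M").to_numpy(float)),
            "group": _standardize(is_case.astype(float)),
        }
        for cov, frac in covariate_effects.items():
            if frac <= 0:
                continue
            if cov not in z:
                raise ValueError(f"unknown covariate {cov!r}")
            coef = math.sqrt(frac * base_var / (1.0 - total_frac))
            # random sign per feature: a shift common to all features would
            # be absorbed into the library size and erased by CPM scaling
            signs = rng.choice(np.array([-1.0, 1.0]), size=n_feat)
            offsets += coef * signs[:, None] * z[cov][None, :]

    mean = 2.0 ** (log2_baseline[:, None] + offsets)
    counts = nb_counts(mean, dispersion, rng)
    return CountMatrix(list(feature_ids), list(metadata["sample"]), counts)


# ---------------------------------------------------------------------------
# study generation


def _matches_with_wildcards(needle: str, window: str) -> bool:
    """Does ``needle`` match ``window`` where '?' in window matches anything?"""
    return all(w in ("?", n) for n, w in zip(needle, window))


def _collides(hexamer: str, context: str, skip_offset: int | None = None) -> bool:
    """Does ``hexamer`` occur anywhere inside the padded motif ``context``
    (with '?' wildcards for unconstrained flanking bases)?  ``skip_offset``
    exempts the motif's own hexamer position from the self-check."""
    return any(
        _matches_with_wildcards(hexamer, context[i : i + 6])
        for i in range(len(context) - 5)
        if i != skip_offset
    )


def _make_mirna_panel(cfg: SimConfig, rng: np.random.Generator) -> list[MiRNA]:
    """Panel of 22-nt miRNAs whose seeds all contain GG, with unique seeds.

    Only the first ``n_sponge_mirnas`` members ever have sites planted, so
    those get "contexts": the seed hexamer padded with two wildcard bases on
    each side (flanks are literal only for 8mer plantings, background
    otherwise, so wildcards are the conservative choice).  Every panel
    hexamer must avoid matching any sponge context at any shifted offset —
    otherwise a planted motif could spawn a spurious site for that member no
    matter what the background looks like.  Background members need no
    constraints among themselves.
    """
    alphabet = "ACGU"
    n_sponge = min(cfg.n_sponge_mirnas, cfg.n_mirnas)
    panel: list[MiRNA] = []
    contexts: list[str] = []  # wildcard-padded motifs of the sponge members
    hexes: list[str] = []
    while len(panel) < cfg.n_mirnas:
        seq = [alphabet[i] for i in rng.integers(0, 4, size=22)]
        gg_at = int(rng.integers(0, 5))  # position of GG inside the seed hexamer
        seed = [alphabet[i] for i in rng.integers(0, 4, size=6)]
        seed[gg_at] = "G"
        seed[gg_at + 1] = "G"
        seq[1:7] = seed
        cand = MiRNA(id=f"sim-miR-{len(panel) + 1:03d}", sequence="".join(seq))
        hexamer = revcomp_rna(cand.seed6)
        if hexamer in hexes:
            continue
        if any(_collides(hexamer, c) for c in contexts):
            continue
        if len(panel) < n_sponge:  # candidate will itself be plantable
            ctx = "??" + hexamer + "??"
            if any(_collides(h, ctx) for h in hexes):
                continue
            if _collides(hexamer, ctx, skip_offset=2):
                continue
            contexts.append(ctx)
        panel.append(cand)
        hexes.append(hexamer)
    return panel


def _split_de(
    ids: Sequence[str], tissues: Sequence[str], n_total: int, frac_up: float,
    rng: np.random.Generator,
) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """Partition n_total DE feature IDs across tissues, disjointly, into
    up/down sets (frac_up of each tissue's share is upregulated)."""
    chosen = list(rng.choice(np.array(ids), size=n_total, replace=False))
    up: dict[str, list[str]] = {}
    down: dict[str, list[str]] = {}
    k = len(tissues)
    base, extra = divmod(n_total, k)
    start = 0
    for i, t in enumerate(tissues):
        share = base + (1 if i < extra else 0)
        block = chosen[start : start + share]
        start += share
        n_up = round(frac_up * len(block))
        up[t] = sorted(block[:n_up])
        down[t] = sorted(block[n_up:])
    return up, down


def _make_junctions(cfg: SimConfig, rng: np.random.Generator):
    """Caller-A and caller-B junction lists sharing exactly
    round(caller_overlap * n_circ) junctions."""
    shared_n = round(cfg.caller_overlap * cfg.n_circ)
    uniq_n = cfg.n_circ - shared_n
    total = shared_n + 2 * uniq_n
    juncs: list[BackspliceJunction] = []
    seen: set[tuple[str, int, int]] = set()
    while len(juncs) < total:
        chrom = f"chr{int(rng.integers(1, 23))}"
        start = int(rng.integers(10_000, 50_000_000))
        end = start + int(rng.integers(300, 20_000))
        if (chrom, start, end) in seen:
            continue
        seen.add((chrom, start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        juncs.append(BackspliceJunction(chrom, start, end, strand))
    shared = juncs[:shared_n]
    only_a = juncs[shared_n : shared_n + uniq_n]
    only_b = juncs[shared_n + uniq_n :]
    return shared, only_a, only_b


def _metadata(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for tissue, (n_case, n_ctrl) in cfg.samples_per_group.items():
        for i in range(n_case):
            rows.append(
                {
                    "sample": f"{tissue}_ALS_{i + 1:02d}",
                    "tissue": tissue,
                    "condition": "ALS",
                    "RIN": round(float(rng.uniform(7.0, 9.5)), 2),
                    "PMI": round(float(rng.uniform(2.0, 15.0)), 1),
                    "sex": "M" if rng.random() < 0.6 else "F",
                }
            )
        for i in range(n_ctrl):
            rows.append(
                {
                    "sample": f"{tissue}_CTL_{i + 1:02d}",
                    "tissue": tissue,
                    "condition": "control",
                    "RIN": round(float(rng.uniform(3.5, 7.3)), 2),
                    "PMI": round(float(rng.uniform(5.0, 25.0)), 1),
                    "sex": "M" if rng.random() < 0.5 else "F",
                }
            )
    return pd.DataFrame(rows)


def _place_sites(
    length: int,
    mirna_types: Sequence[tuple[MiRNA, str]],
    rng: np.random.Generator,
) -> list[tuple[MiRNA, int, str]]:
    """Choose non-overlapping (miRNA, position, type) plantings for one
    circRNA; roughly one site in five wraps the back-spliced junction."""
    placements: list[tuple[MiRNA, int, str]] = []
    occupied: set[int] = set()
    for m, st in mirna_types:
        span = _SPAN[st]
        for _try in range(200):
            if rng.random() < 0.2:  # wrap the junction
                pos = length - int(rng.integers(1, span))
            else:
                pos = int(rng.integers(1, length - span))
            # 3-base buffer: no scan window can touch two motifs
            cells = {(pos - 1 + k) % length for k in range(-3, span + 3)}
            if not (occupied & cells):
                occupied |= cells
                placements.append((m, pos, st))
                break
        else:
            raise RuntimeError("could not place planted sites without overlap")
    return placements


def generate_study(config: SimConfig, outdir: str | Path) -> StudyBundle:
    """Generate the full synthetic study into ``outdir``.

    Deterministic given ``config.seed``: the same configuration and seed
    produce byte-identical files.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    (r_mirna, r_junc, r_meta, r_de, r_seq, r_counts_c, r_counts_g,
     r_jitter, r_targets, r_gmt) = [np.random.default_rng(s) for s in ss.spawn(10)]

    tissues = list(config.samples_per_group)
    panel = _make_mirna_panel(config, r_mirna)
    sponge = panel[: config.n_sponge_mirnas]
    shared, only_a, only_b = _make_junctions(config, r_junc)
    consensus_ids = [j.circ_id for j in shared]
    metadata = _metadata(config, r_meta)

    # ---- truth: DE assignments ------------------------------------------
    n_de_circ = round(config.frac_de_circ * config.n_circ)
    circ_up, circ_down = _split_de(consensus_ids, tissues, n_de_circ, config.frac_up, r_de)
    gene_ids = [f"GENE{i + 1:05d}" for i in range(config.n_genes)]
    n_de_genes = round(config.frac_de_genes * config.n_genes)
    gene_up, gene_down = _split_de(gene_ids, tissues, n_de_genes, config.frac_up, r_de)

    # ---- circRNA sequences with planted sites ---------------------------
    planted_circ = [c for t in sorted(circ_up) for c in circ_up[t]]
    cycle = 0
    mirna_types_by_circ: dict[str, list[tuple[MiRNA, str]]] = {}
    for circ in planted_circ:
        mt: list[tuple[MiRNA, str]] = []
        for m in sponge:
            for _ in range(config.planted_sites_per_circ):
                mt.append((m, _SITE_CYCLE[cycle % len(_SITE_CYCLE)]))
                cycle += 1
        mirna_types_by_circ[circ] = mt

    planted_sites: list[tuple[str, str, int, str]] = []
    circ_seqs: dict[str, str] = {}
    for circ in consensus_ids:
        mt = mirna_types_by_circ.get(circ, [])
        # if local repair cannot reach an exactly-clean sequence for a given
        # site layout, re-draw the positions and try again
        for _attempt in range(30):
            placements = _place_sites(config.circ_length, mt, r_seq)
            try:
                circ_seqs[circ] = _assemble_sequence(
                    config.circ_length, placements, panel, r_seq, max_rounds=80
                )
                break
            except RuntimeError:
                continue
        else:
            raise RuntimeError(f"could not build a clean sequence for {circ}")
        planted_sites.extend(
            (circ, m.id, pos, st)
            for m, pos, st in sorted(placements, key=lambda p: (p[0].id, p[1]))
        )

    # ---- counts ----------------------------------------------------------
    # floor keeps every consensus junction detectable in both callers
    base_circ = np.clip(
        r_counts_c.normal(config.mean_log_expression, config.baseline_log_sd,
                          size=len(consensus_ids)),
        2.0, None,
    )
    lfc_circ = {
        t: {**{f: config.lfc_magnitude for f in circ_up[t]},
            **{f: -config.lfc_magnitude for f in circ_down[t]}}
        for t in tissues
    }
    circ_counts = simulate_counts(
        metadata, consensus_ids, base_circ, lfc_circ, config.nb_dispersion,
        r_counts_c, config.covariate_effects, config.mean_log_expression,
    )
    base_gene = r_counts_g.normal(config.mean_log_expression, config.baseline_log_sd,
                                  size=config.n_genes)
    lfc_gene = {
        t: {**{f: config.lfc_magnitude for f in gene_up[t]},
            **{f: -config.lfc_magnitude for f in gene_down[t]}}
        for t in tissues
    }
    gene_counts = simulate_counts(
        metadata, gene_ids, base_gene, lfc_gene, config.nb_dispersion,
        r_counts_g, config.covariate_effects, config.mean_log_expression,
    )

    # ---- caller tables ---------------------------------------------------
    # caller-specific junctions get their own NB counts
    def _extra_counts(juncs: list[BackspliceJunction], rng: np.random.Generator):
        base = rng.normal(config.mean_log_expression - 2.0, config.baseline_log_sd,
                          size=len(juncs))
        mean = 2.0 ** base[:, None] * np.ones((1, len(metadata)))
        return nb_counts(mean, config.nb_dispersion, rng)

    extra_a = _extra_counts(only_a, r_jitter)
    extra_b = _extra_counts(only_b, r_jitter)

    def _caller_records(caller: str) -> list[CircRecord]:
        jitter_lo, jitter_hi = 0.8, 1.2
        records: list[CircRecord] = []
        shared_counts = circ_counts.counts
        jit = r_jitter.uniform(jitter_lo, jitter_hi, size=shared_counts.shape)
        for i, j in enumerate(shared):
            for k, sample in enumerate(metadata["sample"]):
                reads = round(shared_counts[i, k] * jit[i, k])
                if reads >= 1:
                    records.append(CircRecord(j, sample, float(reads), caller))
        extras, juncs = (extra_a, only_a) if caller == "A" else (extra_b, only_b)
        for i, j in enumerate(juncs):
            for k, sample in enumerate(metadata["sample"]):
                if extras[i, k] >= 1:
                    records.append(CircRecord(j, sample, float(extras[i, k]), caller))
        return records

    records_a = _caller_records("A")
    records_b = _caller_records("B")

    # ---- targets ---------------------------------------------------------
    scanned_tissues = tissues[: min(2, len(tissues))]  # SCC/SCT analogues
    up_pool = sorted({g for t in scanned_tissues for g in gene_up[t]})
    n_aff = min(config.n_affected_genes, len(up_pool))
    affected = sorted(r_targets.choice(np.array(up_pool), size=n_aff, replace=False))
    de_all = {g for t in tissues for g in gene_up[t] + gene_down[t]}
    non_de = [g for g in gene_ids if g not in de_all]
    target_records: list[TargetRecord] = []
    for g in affected:
        k = int(r_targets.integers(1, 4))
        hitters = r_targets.choice(np.array([m.id for m in sponge]), size=k, replace=False)
        for mid in hitters:
            target_records.append(
                TargetRecord(str(mid), g, round(float(r_targets.uniform(-0.6, -0.05)), 3))
            )
    # decoys: sponge miRNAs -> non-DE genes; background miRNAs -> any genes
    for m in sponge:
        for g in r_targets.choice(np.array(non_de), size=3, replace=False):
            target_records.append(
                TargetRecord(m.id, str(g), round(float(r_targets.uniform(-0.6, -0.05)), 3))
            )
    for m in panel[config.n_sponge_mirnas :]:
        for g in r_targets.choice(np.array(gene_ids), size=2, replace=False):
            target_records.append(
                TargetRecord(m.id, str(g), round(float(r_targets.uniform(-0.6, -0.05)), 3))
            )

    # ---- GMT -------------------------------------------------------------
    from .enrichment import GeneSet

    extra_members = [str(g) for g in r_gmt.choice(np.array(non_de), size=10, replace=False)]
    sets = [GeneSet("TERM0001", "planted_enriched_term",
                    frozenset(list(affected) + extra_members))]
    for i in range(2, 21):
        members = r_gmt.choice(np.array(gene_ids), size=50, replace=False)
        sets.append(GeneSet(f"TERM{i:04d}", f"background_term_{i}",
                            frozenset(str(g) for g in members)))

    # ---- write everything ------------------------------------------------
    truth = TruthManifest(
        de_circ_up=circ_up,
        de_circ_down=circ_down,
        de_genes_up=gene_up,
        de_genes_down=gene_down,
        planted_sites=planted_sites,
        enriched_term="TERM0001",
        covariate_effects=dict(config.covariate_effects),
        sponge_mirnas=[m.id for m in sponge],
        affected_genes=[str(g) for g in affected],
        scanned_tissues=list(scanned_tissues),
        consensus_circ_ids=consensus_ids,
        caller_shared=len(shared),
    )
    paths = {
        "caller_table_a": outdir / "caller_a.ciri2_like.tsv",
        "caller_table_b": outdir / "caller_b.circexplorer2_like.tsv",
        "circ_fasta": outdir / "circ_sequences.fasta",
        "mirna_fasta": outdir / "mirna_panel.fasta",
        "circ_counts": outdir / "circ_counts.tsv",
        "gene_counts": outdir / "gene_counts.tsv",
        "metadata": outdir / "metadata.tsv",
        "target_table": outdir / "mirna_targets.tsv",
        "gmt": outdir / "gene_sets.gmt",
        "truth_json": outdir / "truth.json",
    }
    cio.write_caller_table(records_a, paths["caller_table_a"], cio.CIRI2_LIKE)
    cio.write_caller_table(records_b, paths["caller_table_b"], cio.CIRCEXPLORER2_LIKE)
    cio.write_fasta(circ_seqs, paths["circ_fasta"])
    cio.write_fasta({m.id: m.sequence for m in panel}, paths["mirna_fasta"])
    cio.write_counts(circ_counts, paths["circ_counts"])
    cio.write_counts(gene_counts, paths["gene_counts"])
    cio.write_metadata(metadata, paths["metadata"])
    cio.write_targets(target_records, paths["target_table"])
    cio.write_gmt(sets, paths["gmt"])
    truth.to_json(paths["truth_json"])

    return StudyBundle(outdir=outdir, truth=truth, **paths)
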