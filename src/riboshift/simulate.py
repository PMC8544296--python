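"""Synthetic transcriptome and paired RNA/RPF libraries with known truth.

The generator emulates a two-arm (optionally three-arm) ribosome-profiling
experiment: a control condition, a stress condition in which designated
genes change transcript abundance, translation efficiency, or shift
ribosome density out of the 5'UTR into the CDS (uORF bypass), and an
optional reversal arm in which every effect is scaled back toward control.

Per library, gene-level counts are negative-binomial: each biological
replicate draws one gamma factor per gene (shape 1/dispersion) that is
shared between the RNA and RPF libraries of that replicate — both are
sequenced from the same lysate — and reads are then allocated by a single
multinomial draw, so each library contains exactly the configured number
of reads.  RPF placement follows the configured region occupancies and
frame-0 probability, with the P-site convention used for read placement
recorded in the config; RNA reads are uniform over the transcript.

Everything is reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import TranscriptModel, write_bed12
from .io import write_alignments_sam, write_alignments_tsv

__all__ = [
    "SimConfig",
    "SimConfigError",
    "SimResult",
    "simulate",
    "simulate_transcriptome",
    "simulate_reads",
    "write_outputs",
]

_NONSTOP_CODONS = np.array(
    [a + b + c
     for a in "ACGT" for b in "ACGT" for c in "ACGT"
     if a + b + c not in ("TAA", "TAG", "TGA")]
)
_STOP_CODONS = np.array(["TAA", "TAG", "TGA"])


class SimConfigError(ValueError):
    """Raised for infeasible or inconsistent simulation settings."""


@dataclass
class SimConfig:
    """Ground-truth design of one synthetic experiment.

    Defaults describe the emulated study: two conditions x two biological
    replicates, 2M reads per library, NB dispersion 0.1, ~30-nt RPFs with
    3-nt periodicity (75% frame 0) concentrated on the CDS, and gene
    subsets with transcription-level changes, TE changes, or a
    treatment-induced 5'UTR -> CDS occupancy shift.
    """

    n_genes: int = 1000
    seed: int = 0
    conditions: tuple[str, ...] = ("control", "treated")
    control_condition: str = "control"
    n_replicates: int = 2
    reads_per_library: int = 2_000_000
    nb_dispersion: float = 0.1

    # transcript architecture: lognormal lengths (log-scale mean/sd) + floors
    utr5_meanlog: float = 5.2
    utr5_sdlog: float = 0.5
    min_utr5: int = 60
    cds_meanlog: float = 7.0
    cds_sdlog: float = 0.5
    min_cds: int = 300
    utr3_meanlog: float = 6.0
    utr3_sdlog: float = 0.6
    min_utr3: int = 60

    # expression heterogeneity (lognormal, log-scale sd)
    abundance_sdlog: float = 1.2
    te_sdlog: float = 0.8

    # uORF architecture and its baseline repression of TE
    uorf_fraction: float = 0.2
    kozak_mix: dict = field(
        default_factory=lambda: {"strong": 0.4, "adequate": 0.3, "weak": 0.3}
    )
    uorf_te_repression: dict = field(
        default_factory=lambda: {"strong": 0.5, "adequate": 0.7, "weak": 0.85}
    )

    # per-condition effects (fractions of genes; disjoint sets)
    te_up_fraction: float = 0.1
    te_down_fraction: float = 0.1
    te_effect_log2: float = 2.0
    rna_up_fraction: float = 0.02
    rna_down_fraction: float = 0.02
    rna_effect_log2: float = 2.0
    uorf_shift_fraction: float = 0.1
    shift_utr5_occupancy: tuple[float, float] = (0.4, 0.1)  # (control, treated)
    uorf_utr5_occupancy: float = 0.25  # non-shift uORF genes, both conditions
    base_utr5_occupancy: float = 0.055
    base_utr3_occupancy: float = 0.027

    # RPF model
    frame0_prob: float = 0.75
    rpf_length_probs: dict = field(
        default_factory=lambda: {28: 0.10, 29: 0.20, 30: 0.40, 31: 0.20, 32: 0.10}
    )
    rna_read_length: int = 50
    psite_offset: int = 12

    # optional reversal arm ("treated_nac"): effects scaled toward control
    reversal_factor: float = 0.9

    def validate(self) -> None:
        fracs = {
            "uorf_fraction": self.uorf_fraction,
            "te_up_fraction": self.te_up_fraction,
            "te_down_fraction": self.te_down_fraction,
            "rna_up_fraction": self.rna_up_fraction,
            "rna_down_fraction": self.rna_down_fraction,
            "uorf_shift_fraction": self.uorf_shift_fraction,
            "frame0_prob": self.frame0_prob,
            "base_utr5_occupancy": self.base_utr5_occupancy,
            "base_utr3_occupancy": self.base_utr3_occupancy,
            "uorf_utr5_occupancy": self.uorf_utr5_occupancy,
        }
        for name, f in fracs.items():
            if not 0.0 <= f <= 1.0:
                raise SimConfigError(f"{name}={f} outside [0, 1]")
        n_effect = (
            self.te_up_fraction + self.te_down_fraction + self.rna_up_fraction
            + self.rna_down_fraction + self.uorf_shift_fraction
        )
        if n_effect > 1.0:
            raise SimConfigError("effect-gene fractions sum above 1; sets cannot be disjoint")
        for occ in (*self.shift_utr5_occupancy, self.uorf_utr5_occupancy):
            if not 0.0 <= occ + self.base_utr3_occupancy < 1.0:
                raise SimConfigError("5'UTR + 3'UTR occupancy must leave CDS mass")
        any_uorf = self.uorf_fraction > 0 or self.uorf_shift_fraction > 0
        if any_uorf and self.min_utr5 < 20:
            raise SimConfigError(
                f"min_utr5={self.min_utr5} too short to plant a uORF with its "
                "Kozak context (need >= 20 nt)"
            )
        if self.min_cds < 9 or self.min_utr3 < 1:
            raise SimConfigError("CDS needs >= 3 codons and 3'UTR >= 1 nt")
        utr5_used = max(
            self.base_utr5_occupancy, self.uorf_utr5_occupancy, *self.shift_utr5_occupancy
        )
        if utr5_used > 0 and self.min_utr5 < 1:
            raise SimConfigError("5'UTR occupancy > 0 requires min_utr5 >= 1")
        if abs(sum(self.kozak_mix.values()) - 1.0) > 1e-9:
            raise SimConfigError("kozak_mix must sum to 1")
        if abs(sum(self.rpf_length_probs.values()) - 1.0) > 1e-9:
            raise SimConfigError("rpf_length_probs must sum to 1")
        if self.control_condition not in self.conditions:
            raise SimConfigError("control_condition must be one of conditions")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conditions"] = list(self.conditions)
        d["shift_utr5_occupancy"] = list(self.shift_utr5_occupancy)
        return d


@dataclass
class SimResult:
    config: SimConfig
    models: list[TranscriptModel]
    truth: pd.DataFrame
    sample_sheet: pd.DataFrame
    alignments: dict[tuple[str, str], pd.DataFrame]  # (sample_id, library) -> reads


# ---------------------------------------------------------------------------
# gene roles and architecture
# ---------------------------------------------------------------------------

def _assign_roles(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_genes
    perm = rng.permutation(n)
    sizes = {
        "te_up": int(round(cfg.te_up_fraction * n)),
        "te_down": int(round(cfg.te_down_fraction * n)),
        "rna_up": int(round(cfg.rna_up_fraction * n)),
        "rna_down": int(round(cfg.rna_down_fraction * n)),
        "uorf_shift": int(round(cfg.uorf_shift_fraction * n)),
    }
    role = np.full(n, "null", dtype=object)
    pos = 0
    for name, size in sizes.items():
        role[perm[pos : pos + size]] = name
        pos += size

    has_uorf = role == "uorf_shift"
    n_extra = max(0, int(round(cfg.uorf_fraction * n)) - has_uorf.sum())
    candidates = perm[pos:]
    has_uorf[candidates[:n_extra]] = True

    kozak = np.full(n, "", dtype=object)
    classes = list(cfg.kozak_mix)
    probs = np.array([cfg.kozak_mix[c] for c in classes])
    kozak[has_uorf] = rng.choice(classes, size=int(has_uorf.sum()), p=probs)

    return pd.DataFrame(
        {
            "gene_id": [f"G{i:05d}" for i in range(n)],
            "transcript_id": [f"G{i:05d}.1" for i in range(n)],
            "role": role,
            "has_uorf": has_uorf,
            "kozak": kozak,
        }
    )


def _draw_lengths(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_genes
    utr5 = np.maximum(
        cfg.min_utr5, rng.lognormal(cfg.utr5_meanlog, cfg.utr5_sdlog, n).astype(int)
    )
    cds = np.maximum(
        cfg.min_cds, rng.lognormal(cfg.cds_meanlog, cfg.cds_sdlog, n).astype(int)
    )
    cds = (cds // 3) * 3
    utr3 = np.maximum(
        cfg.min_utr3, rng.lognormal(cfg.utr3_meanlog, cfg.utr3_sdlog, n).astype(int)
    )
    return pd.DataFrame({"utr5_len": utr5, "cds_len": cds, "utr3_len": utr3})


def _plant_uorf(
    utr5: np.ndarray, kozak: str, cds_start: int, rng: np.random.Generator
) -> int:
    """Write an AUG with the requested Kozak context into a 5'UTR array."""
    pos = int(rng.integers(3, cds_start - 13))
    utr5[pos : pos + 3] = list("ATG")
    if kozak == "strong":
        utr5[pos - 3] = rng.choice(list("AG"))
        utr5[pos + 3] = "G"
    elif kozak == "adequate":
        if rng.random() < 0.5:
            utr5[pos - 3] = rng.choice(list("AG"))
            utr5[pos + 3] = rng.choice(list("ACT"))
        else:
            utr5[pos - 3] = rng.choice(list("CT"))
            utr5[pos + 3] = "G"
    else:  # weak
        utr5[pos - 3] = rng.choice(list("CT"))
        utr5[pos + 3] = rng.choice(list("ACT"))
    # close the uORF inside the 5'UTR when there is room; otherwise it
    # runs on and overlaps the CDS (ATF4-style configuration)
    max_k = (cds_start - pos - 3) // 3  # stop codon slots within the UTR
    if max_k >= 2:
        k = int(rng.integers(2, max_k + 1))
        stop = rng.choice(_STOP_CODONS)
        utr5[pos + 3 * k : pos + 3 * k + 3] = list(stop)
    return pos


def simulate_transcriptome(
    cfg: SimConfig, roles: pd.DataFrame | None = None
) -> tuple[list[TranscriptModel], pd.DataFrame]:
    """Generate transcript models with sequences and architecture truth.

    Sequences contain the declared uORFs at recorded positions with the
    requested Kozak context; each CDS starts with AUG, contains no
    premature in-frame stop, and ends with a stop codon.
    """
    cfg.validate()
    seq_root, role_root = np.random.SeedSequence(cfg.seed).spawn(2)
    if roles is None:
        roles = _assign_roles(cfg, np.random.default_rng(role_root))
    rng = np.random.default_rng(seq_root)
    lengths = _draw_lengths(cfg, rng)

    bases = np.array(list("ACGT"))
    models: list[TranscriptModel] = []
    uaug_pos = np.full(cfg.n_genes, -1, dtype=int)
    for i in range(cfg.n_genes):
        u5, cds_len, u3 = (
            int(lengths.at[i, "utr5_len"]),
            int(lengths.at[i, "cds_len"]),
            int(lengths.at[i, "utr3_len"]),
        )
        utr5 = rng.choice(bases, size=u5)
        if roles.at[i, "has_uorf"]:
            uaug_pos[i] = _plant_uorf(utr5, roles.at[i, "kozak"], u5, rng)
        n_codons = cds_len // 3
        body = rng.choice(_NONSTOP_CODONS, size=n_codons - 2)
        cds = "ATG" + "".join(body) + rng.choice(_STOP_CODONS)
        utr3 = rng.choice(bases, size=u3)
        seq = "".join(utr5) + cds + "".join(utr3)
        models.append(
            TranscriptModel(
                transcript_id=roles.at[i, "transcript_id"],
                gene_id=roles.at[i, "gene_id"],
                length=u5 + cds_len + u3,
                cds_start=u5,
                cds_end=u5 + cds_len,
                sequence=seq,
            )
        )
    arch = pd.concat([roles, lengths], axis=1)
    arch["uaug_pos"] = uaug_pos
    return models, arch


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _condition_params(cfg: SimConfig, arch: pd.DataFrame, rng: np.random.Generator):
    """Per-gene abundance, TE and region occupancies for every condition."""
    n = cfg.n_genes
    abundance = rng.lognormal(0.0, cfg.abundance_sdlog, n)
    te_basal = rng.lognormal(0.0, cfg.te_sdlog, n)
    for cls, factor in cfg.uorf_te_repression.items():
        te_basal[(arch["has_uorf"] & (arch["kozak"] == cls)).to_numpy()] *= factor

    role = arch["role"].to_numpy()
    params: dict[str, dict[str, np.ndarray]] = {}
    for cond in cfg.conditions:
        if cond == cfg.control_condition:
            scale = 0.0
        elif cond.endswith("_nac"):
            scale = 1.0 - cfg.reversal_factor
        else:
            scale = 1.0
        rna = abundance * np.where(
            role == "rna_up", 2.0 ** (cfg.rna_effect_log2 * scale),
            np.where(role == "rna_down", 2.0 ** (-cfg.rna_effect_log2 * scale), 1.0),
        )
        te = te_basal * np.where(
            role == "te_up", 2.0 ** (cfg.te_effect_log2 * scale),
            np.where(role == "te_down", 2.0 ** (-cfg.te_effect_log2 * scale), 1.0),
        )
        occ_ctrl, occ_treat = cfg.shift_utr5_occupancy
        shift_occ = occ_ctrl + (occ_treat - occ_ctrl) * scale
        p_utr5 = np.where(
            role == "uorf_shift", shift_occ,
            np.where(arch["has_uorf"], cfg.uorf_utr5_occupancy, cfg.base_utr5_occupancy),
        )
        p_utr3 = np.full(n, cfg.base_utr3_occupancy)
        params[cond] = {"rna": rna, "te": te, "p_utr5": p_utr5, "p_utr3": p_utr3}
    return params


def _place_rpf(
    counts: np.ndarray,
    arch: pd.DataFrame,
    p_utr5: np.ndarray,
    p_utr3: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-read transcript placement for one RPF library."""
    gene = np.repeat(np.arange(len(counts)), counts)
    n = gene.size
    u5 = arch["utr5_len"].to_numpy()[gene]
    cds_len = arch["cds_len"].to_numpy()[gene]
    u3 = arch["utr3_len"].to_numpy()[gene]
    tx_len = u5 + cds_len + u3

    u = rng.random(n)
    region = np.where(u < p_utr5[gene], 0, np.where(u < (p_utr5 + p_utr3)[gene], 2, 1))

    lengths_arr = np.array(sorted(cfg.rpf_length_probs))
    probs = np.array([cfg.rpf_length_probs[k] for k in lengths_arr])
    read_len = rng.choice(lengths_arr, size=n, p=probs)

    psite = np.empty(n, dtype=np.int64)
    m = region == 0
    if m.any():
        psite[m] = rng.integers(0, u5[m])
    m = region == 2
    if m.any():
        psite[m] = u5[m] + cds_len[m] + rng.integers(0, u3[m])
    m = region == 1
    if m.any():
        v = rng.random(m.sum())
        f0 = cfg.frame0_prob
        frame = np.where(v < f0, 0, np.where(v < f0 + (1 - f0) / 2, 1, 2))
        codon = rng.integers(0, cds_len[m] // 3)
        psite[m] = u5[m] + 3 * codon + frame

    start = np.clip(psite - cfg.psite_offset, 0, tx_len - read_len)
    tx_ids = arch["transcript_id"].to_numpy()[gene]
    return pd.DataFrame(
        {"transcript_id": tx_ids, "start": start, "read_length": read_len}
    )


def _place_rna(
    counts: np.ndarray, arch: pd.DataFrame, cfg: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    gene = np.repeat(np.arange(len(counts)), counts)
    tx_len = (arch["utr5_len"] + arch["cds_len"] + arch["utr3_len"]).to_numpy()[gene]
    read_len = np.minimum(cfg.rna_read_length, tx_len)
    start = rng.integers(0, tx_len - read_len + 1)
    return pd.DataFrame(
        {
            "transcript_id": arch["transcript_id"].to_numpy()[gene],
            "start": start,
            "read_length": read_len,
        }
    )


def simulate_reads(
    cfg: SimConfig, arch: pd.DataFrame
) -> tuple[dict[tuple[str, str], pd.DataFrame], pd.DataFrame, pd.DataFrame]:
    """Generate paired RNA/RPF alignments for every sample, plus truth.

    Returns (alignments keyed by (sample_id, library), truth table,
    sample sheet).  Expected RNA reads per gene are proportional to
    abundance x transcript length; expected RPF reads to abundance x TE x
    CDS length, split across regions by the gene's occupancies, so the
    measurable CDS-density TE of a gene is te x p_cds.
    """
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed).spawn(3)
    rng = np.random.default_rng(root[2])
    params = _condition_params(cfg, arch, rng)

    tx_len = (arch["utr5_len"] + arch["cds_len"] + arch["utr3_len"]).to_numpy()
    cds_len = arch["cds_len"].to_numpy()
    shape = 1.0 / cfg.nb_dispersion

    alignments: dict[tuple[str, str], pd.DataFrame] = {}
    sheet_rows = []
    for cond in cfg.conditions:
        p = params[cond]
        for rep in range(1, cfg.n_replicates + 1):
            sample = f"{cond}_rep{rep}"
            rep_factor = rng.gamma(shape, cfg.nb_dispersion, cfg.n_genes)
            rna_w = p["rna"] * tx_len * rep_factor
            rpf_w = p["rna"] * p["te"] * cds_len * rep_factor
            rna_counts = rng.multinomial(cfg.reads_per_library, rna_w / rna_w.sum())
            rpf_counts = rng.multinomial(cfg.reads_per_library, rpf_w / rpf_w.sum())
            alignments[(sample, "rna")] = _place_rna(rna_counts, arch, cfg, rng)
            alignments[(sample, "rpf")] = _place_rpf(
                rpf_counts, arch, p["p_utr5"], p["p_utr3"], cfg, rng
            )
            sheet_rows += [
                (sample, cond, rep, "rna"),
                (sample, cond, rep, "rpf"),
            ]

    sheet = pd.DataFrame(
        sheet_rows, columns=["sample_id", "condition", "replicate", "library"]
    )

    truth = arch.copy()
    ctrl = cfg.control_condition
    treat = next(
        (c for c in cfg.conditions if c != ctrl and not c.endswith("_nac")), ctrl
    )
    for cond in cfg.conditions:
        p = params[cond]
        p_cds = 1.0 - p["p_utr5"] - p["p_utr3"]
        truth[f"abundance_{cond}"] = p["rna"]
        truth[f"te_{cond}"] = p["te"]
        truth[f"utr5_occ_{cond}"] = p["p_utr5"]
        truth[f"te_eff_{cond}"] = p["te"] * p_cds
    truth["true_rna_log2fc"] = np.log2(
        truth[f"abundance_{treat}"] / truth[f"abundance_{ctrl}"]
    )
    truth["true_te_log2fc"] = np.log2(truth[f"te_eff_{treat}"] / truth[f"te_eff_{ctrl}"])
    return alignments, truth, sheet


def simulate(cfg: SimConfig) -> SimResult:
    """End-to-end simulation: transcriptome, libraries, truth, sample sheet."""
    models, arch = simulate_transcriptome(cfg)
    alignments, truth, sheet = simulate_reads(cfg, arch)
    return SimResult(cfg, models, truth, sheet, alignments)


# ---------------------------------------------------------------------------
# on-disk outputs
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_outputs(
    sim: SimResult, outdir: str | Path, alignment_format: str = "tsv"
) -> dict[str, str]:
    """Write FASTA, BED12, alignments, truth, config echo and a manifest.

    Returns the manifest (relative path -> sha256).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    fasta = outdir / "transcriptome.fa"
    with open(fasta, "w") as fh:
        for m in sim.models:
            fh.write(f">{m.transcript_id}\n")
            for i in range(0, m.length, 70):
                fh.write(m.sequence[i : i + 70] + "\n")
    write_bed12(sim.models, outdir / "transcripts.bed")
    sim.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    sim.sample_sheet.to_csv(outdir / "samples.tsv", sep="\t", index=False)

    import yaml

    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(sim.config.to_dict(), fh, sort_keys=True)

    for (sample, library), df in sim.alignments.items():
        if alignment_format == "sam":
            write_alignments_sam(df, sim.models, outdir / f"{sample}_{library}.sam")
        else:
            write_alignments_tsv(df, outdir / f"{sample}_{library}.tsv")

    manifest = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
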