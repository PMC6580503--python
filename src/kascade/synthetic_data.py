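"""Self-contained synthetic datasets with the statistical structure the
predictor assumes, so the full pipeline is testable without any download.

The generator emits a bundle of proteins (FASTA), labelled lysine sites
(TSV), per-protein ASCII PSSMs, per-residue structure annotations (TSV) and a
ground-truth manifest (YAML).  Planted class contrasts mirror what is
reported for real human acetylation data:

* **sequence** — lysine strongly enriched at position +1 of positive sites
  (and mildly at positions +/-2, +/-3); serine depleted at +1..+4;
* **secondary structure** — positive site residues strand-enriched with zero
  beta-bridge mass; negatives follow the background state distribution;
* **ASA** — positive site residues drawn from a high-exposure component
  centred in the 60-150 square-angstrom range, negatives from a buried/low
  mixture with extra mass below 10;
* **PSSM** — integer log-odds from Dirichlet-perturbed background
  frequencies, with stronger conservation immediately downstream of positive
  sites.

The default negative:positive ratio is 10:1, the imbalance regime the
cascade classifier is designed for.  Identical seeds give byte-identical
bundles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .feature_encoding import (
    PSSM_ALPHABET,
    PSSMMatrix,
    StructureAnnotation,
    read_ascii_pssm,
    read_structure_tsv,
    write_ascii_pssm,
    write_structure_tsv,
)
from .sequence_io import (
    STANDARD_AA,
    PeptideWindow,
    Protein,
    SiteRecord,
    read_fasta,
    read_site_table,
    site_windows,
    write_fasta,
    write_site_table,
)

#: Background amino-acid frequencies (UniProt-like), alphabetical A..Y order.
BACKGROUND_AA_FREQS: dict[str, float] = {
    "A": 0.0826, "C": 0.0137, "D": 0.0546, "E": 0.0674, "F": 0.0386,
    "G": 0.0707, "H": 0.0227, "I": 0.0593, "K": 0.0582, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0472, "Q": 0.0393, "R": 0.0553,
    "S": 0.0660, "T": 0.0535, "V": 0.0687, "W": 0.0110, "Y": 0.0292,
}

_DEF_SS_NEGATIVE = {
    "H": 0.32, "E": 0.18, "B": 0.03, "G": 0.04, "I": 0.01,
    "T": 0.11, "S": 0.09, "-": 0.22,
}
_DEF_SS_POSITIVE = {
    "H": 0.24, "E": 0.28, "B": 0.00, "G": 0.04, "I": 0.01,
    "T": 0.12, "S": 0.09, "-": 0.22,
}


class GeneratorConfigError(ValueError):
    """Invalid or infeasible generator configuration."""


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic bundle.

    The defaults model a mid-size benchmark: 300 proteins, 200 positive and
    2000 negative sites (10:1), window flank 9, with moderate planted signal
    in sequence, structure and conservation.
    """

    n_proteins: int = 300
    min_length: int = 80
    max_length: int = 300
    n_positive: int = 200
    n_negative: int = 2000
    flank: int = 9
    # sequence effect sizes (positive class)
    k_plus1_prob: float = 0.25       # P(K) at position +1
    k_near_prob: float = 0.12        # P(K) at positions -3,-2,+2,+3
    s_depletion_factor: float = 0.10  # multiplier on P(S) at +1..+4
    # structure effect sizes
    ss_negative: dict = field(default_factory=lambda: dict(_DEF_SS_NEGATIVE))
    ss_positive: dict = field(default_factory=lambda: dict(_DEF_SS_POSITIVE))
    asa_positive_mean: float = 75.0
    asa_positive_sd: float = 35.0
    asa_negative_exp_weight: float = 0.35  # buried component weight
    asa_negative_exp_scale: float = 8.0
    asa_negative_norm_mean: float = 35.0
    asa_negative_norm_sd: float = 25.0
    asa_background_mean: float = 40.0
    asa_background_sd: float = 28.0
    # PSSM parameters
    pssm_dirichlet_concentration: float = 10.0
    pssm_background_conservation: float = 0.25
    pssm_positive_downstream_conservation: float = 0.33
    seed: int = 0

    @classmethod
    def null(cls, **overrides) -> "GeneratorConfig":
        """A no-signal configuration: both classes drawn from the background."""
        bg_k = BACKGROUND_AA_FREQS["K"]
        cfg = cls(
            k_plus1_prob=bg_k,
            k_near_prob=bg_k,
            s_depletion_factor=1.0,
            ss_positive=dict(_DEF_SS_NEGATIVE),
            asa_positive_mean=0.0,  # unused: flagged by null_asa below
            pssm_positive_downstream_conservation=0.25,
        )
        cfg._null_asa = True  # type: ignore[attr-defined]
        for k, v in overrides.items():
            setattr(cfg, k, v)
        return cfg

    def validate(self) -> None:
        if self.n_proteins < 1 or self.min_length < 2 * self.flank + 1:
            raise GeneratorConfigError("proteins must exist and exceed one window")
        if self.min_length > self.max_length:
            raise GeneratorConfigError("min_length > max_length")
        if self.n_positive < 1 or self.n_negative < 1:
            raise GeneratorConfigError("site counts must be positive")
        for name in ("k_plus1_prob", "k_near_prob"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise GeneratorConfigError(f"{name} must be in (0, 1)")
        if not 0 < self.s_depletion_factor <= 1:
            raise GeneratorConfigError("s_depletion_factor must be in (0, 1]")
        for name in ("ss_negative", "ss_positive"):
            d = getattr(self, name)
            total = sum(d.values())
            if min(d.values()) < 0 or abs(total - 1.0) > 1e-6:
                raise GeneratorConfigError(f"{name} must be a probability distribution")
        if not 0 <= self.pssm_background_conservation <= 1:
            raise GeneratorConfigError("pssm conservation weights must be in [0, 1]")


@dataclass
class Bundle:
    """An in-memory dataset: proteins, sites, PSSMs, structures, manifest."""

    proteins: list[Protein]
    sites: list[SiteRecord]
    pssms: dict[str, PSSMMatrix]
    structures: dict[str, StructureAnnotation]
    manifest: dict

    def windows(self, flank: int | None = None) -> list[PeptideWindow]:
        flank = flank if flank is not None else int(self.manifest.get("flank", 9))
        return site_windows(self.proteins, self.sites, flank=flank)

    @property
    def n_positive(self) -> int:
        return sum(s.label == 1 for s in self.sites)

    @property
    def n_negative(self) -> int:
        return sum(s.label == 0 for s in self.sites)

    def write(self, outdir: str | Path) -> Path:
        """Write the bundle to disk (FASTA, TSVs, ASCII PSSMs, YAML manifest)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.proteins, outdir / "proteins.fasta")
        write_site_table(self.sites, outdir / "sites.tsv")
        write_structure_tsv(
            [self.structures[p.id] for p in self.proteins], outdir / "structure.tsv"
        )
        pssm_dir = outdir / "pssm"
        pssm_dir.mkdir(exist_ok=True)
        for p in self.proteins:
            write_ascii_pssm(self.pssms[p.id], pssm_dir / f"{p.id}.pssm")
        with open(outdir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(self.manifest, fh, sort_keys=True)
        return outdir


def load_bundle(path: str | Path) -> Bundle:
    """Read a bundle previously written by :meth:`Bundle.write`."""
    path = Path(path)
    proteins = read_fasta(path / "proteins.fasta")
    sites = read_site_table(path / "sites.tsv", proteins)
    structures = read_structure_tsv(path / "structure.tsv")
    pssms = {
        p.id: read_ascii_pssm(path / "pssm" / f"{p.id}.pssm", protein=p)
        for p in proteins
    }
    manifest = {}
    mf = path / "manifest.yaml"
    if mf.exists():
        with open(mf) as fh:
            manifest = yaml.safe_load(fh) or {}
    return Bundle(proteins=proteins, sites=sites, pssms=pssms,
                  structures=structures, manifest=manifest)


_AA_LIST = list(STANDARD_AA)
_BG_VEC = np.array([BACKGROUND_AA_FREQS[a] for a in STANDARD_AA])
_BG_VEC = _BG_VEC / _BG_VEC.sum()


def _positive_flank_dists(cfg: GeneratorConfig) -> dict[int, np.ndarray]:
    """Class-conditional residue distribution for each positive flank position."""
    out = {}
    k_idx = STANDARD_AA.index("K")
    s_idx = STANDARD_AA.index("S")
    for rel in range(-cfg.flank, cfg.flank + 1):
        if rel == 0:
            continue
        p = _BG_VEC.copy()
        if 1 <= rel <= 4:
            p[s_idx] *= cfg.s_depletion_factor
            p = p / p.sum()
        k_target = None
        if rel == 1:
            k_target = cfg.k_plus1_prob
        elif rel in (-3, -2, 2, 3):
            k_target = cfg.k_near_prob
        if k_target is not None:
            rest = 1.0 - k_target
            scale = rest / (1.0 - p[k_idx])
            p = p * scale
            p[k_idx] = k_target
        out[rel] = p
    return out


def _draw_asa(cfg: GeneratorConfig, rng: np.random.Generator, positive: bool) -> float:
    if positive and not getattr(cfg, "_null_asa", False):
        v = rng.normal(cfg.asa_positive_mean, cfg.asa_positive_sd)
    else:
        if rng.random() < cfg.asa_negative_exp_weight:
            v = rng.exponential(cfg.asa_negative_exp_scale)
        else:
            v = abs(rng.normal(cfg.asa_negative_norm_mean, cfg.asa_negative_norm_sd))
    return float(np.clip(v, 0.0, 220.0))


def generate(config: GeneratorConfig | None = None) -> Bundle:
    """Generate one synthetic bundle under ``config`` (defaults when None).

    Site slots are laid out one window width apart inside each protein so
    planted flank compositions never overlap; slots are shuffled and assigned
    to the positive / negative classes.  Raises
    :class:`GeneratorConfigError` when the requested site counts exceed the
    available slots.
    """
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    width = 2 * cfg.flank + 1

    # --- sequences and site slots -----------------------------------------
    seqs: dict[str, np.ndarray] = {}
    proteins_order: list[str] = []
    slots: list[tuple[str, int]] = []
    for i in range(cfg.n_proteins):
        pid = f"SYN{i:04d}"
        proteins_order.append(pid)
        L = int(rng.integers(cfg.min_length, cfg.max_length + 1))
        seqs[pid] = rng.choice(_AA_LIST, size=L, p=_BG_VEC)
        start = int(rng.integers(1, width + 1))
        slots.extend((pid, pos) for pos in range(start, L + 1, width))

    n_sites = cfg.n_positive + cfg.n_negative
    if n_sites > len(slots):
        raise GeneratorConfigError(
            f"requested {n_sites} sites but only {len(slots)} lysine slots are "
            f"available; increase n_proteins or protein lengths"
        )
    order = rng.permutation(len(slots))
    chosen = [slots[j] for j in order[:n_sites]]
    sites = [
        SiteRecord(protein_id=pid, position=pos, label=1 if j < cfg.n_positive else 0)
        for j, (pid, pos) in enumerate(chosen)
    ]

    # plant lysine centres, then the positive flank composition
    pos_dists = _positive_flank_dists(cfg)
    for s in sites:
        seqs[s.protein_id][s.position - 1] = "K"
    for s in sites:
        if s.label != 1:
            continue
        seq = seqs[s.protein_id]
        for rel, dist in pos_dists.items():
            p = s.position + rel
            if 1 <= p <= len(seq):
                seq[p - 1] = rng.choice(_AA_LIST, p=dist)

    proteins = [Protein(id=pid, sequence="".join(seqs[pid])) for pid in proteins_order]
    by_id = {p.id: p for p in proteins}

    # --- structure annotations --------------------------------------------
    neg_states = sorted(cfg.ss_negative)
    neg_probs = np.array([cfg.ss_negative[k] for k in neg_states])
    neg_probs = neg_probs / neg_probs.sum()
    pos_states = sorted(cfg.ss_positive)
    pos_probs = np.array([cfg.ss_positive[k] for k in pos_states])
    pos_probs = pos_probs / pos_probs.sum()

    structures: dict[str, StructureAnnotation] = {}
    for pid in proteins_order:
        L = len(by_id[pid])
        ss = rng.choice(neg_states, size=L, p=neg_probs)
        asa = np.abs(rng.normal(cfg.asa_background_mean, cfg.asa_background_sd, size=L))
        asa = np.clip(asa, 0.0, 220.0)
        structures[pid] = StructureAnnotation(pid, "".join(ss), np.round(asa, 1))
    for s in sites:
        ann = structures[s.protein_id]
        states, probs = (pos_states, pos_probs) if s.label == 1 else (neg_states, neg_probs)
        letter = str(rng.choice(states, p=probs))
        ann.ss = ann.ss[: s.position - 1] + letter + ann.ss[s.position :]
        ann.asa[s.position - 1] = round(_draw_asa(cfg, rng, s.label == 1), 1)

    # --- PSSMs --------------------------------------------------------------
    # Dirichlet-perturbed background mixed with a one-hot on the true residue;
    # the mixing weight is the conservation level, raised downstream of
    # positive sites.
    bg_pssm = np.array([BACKGROUND_AA_FREQS[a] for a in PSSM_ALPHABET])
    bg_pssm = bg_pssm / bg_pssm.sum()
    aa_to_col = {a: i for i, a in enumerate(PSSM_ALPHABET)}
    conserved: dict[str, set[int]] = {pid: set() for pid in proteins_order}
    for s in sites:
        if s.label == 1:
            L = len(by_id[s.protein_id])
            for rel in range(1, cfg.flank + 1):
                p = s.position + rel
                if 1 <= p <= L:
                    conserved[s.protein_id].add(p)

    pssms: dict[str, PSSMMatrix] = {}
    alpha = cfg.pssm_dirichlet_concentration * 20.0 * bg_pssm
    for pid in proteins_order:
        seq = by_id[pid].sequence
        L = len(seq)
        gam = rng.gamma(np.broadcast_to(alpha, (L, 20)))
        p0 = gam / gam.sum(axis=1, keepdims=True)
        w = np.full(L, cfg.pssm_background_conservation)
        for p in conserved[pid]:
            w[p - 1] = cfg.pssm_positive_downstream_conservation
        onehot = np.zeros((L, 20))
        for i, aa in enumerate(seq):
            onehot[i, aa_to_col[aa]] = 1.0
        p_final = (1 - w[:, None]) * p0 + w[:, None] * onehot
        p_final = np.maximum(p_final, 1e-4)
        scores = np.clip(np.rint(2.0 * np.log2(p_final / bg_pssm)), -12, 12)
        pssms[pid] = PSSMMatrix(
            protein_id=pid, letters=PSSM_ALPHABET,
            scores=scores.astype(np.int32), sequence=seq,
        )

    manifest = {
        "generator": "kascade.synthetic_data",
        "flank": cfg.flank,
        "config": _config_dict(cfg),
        "n_proteins": cfg.n_proteins,
        "n_positive": cfg.n_positive,
        "n_negative": cfg.n_negative,
        "seed": cfg.seed,
    }
    return Bundle(proteins=proteins, sites=sites, pssms=pssms,
                  structures=structures, manifest=manifest)


def _config_dict(cfg: GeneratorConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["null_asa"] = bool(getattr(cfg, "_null_asa", False))
    return d


def split_bundle(
    bundle: Bundle,
    fractions: Sequence[float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    names: Sequence[str] | None = None,
) -> list[Bundle]:
    """Partition a bundle BY PROTEIN into len(fractions) sub-bundles.

    Proteins are shuffled (seeded) and assigned to contiguous chunks whose
    sizes follow ``fractions`` (which must sum to 1); every site follows its
    protein, so no protein appears in two splits.
    """
    fractions = list(fractions)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    if any(f <= 0 for f in fractions):
        raise ValueError("fractions must be positive")
    names = list(names) if names is not None else [f"split{i}" for i in range(len(fractions))]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(bundle.proteins))
    n = len(bundle.proteins)
    bounds = np.floor(np.cumsum(fractions) * n + 0.5).astype(int)
    bounds[-1] = n
    out: list[Bundle] = []
    start = 0
    for name, stop in zip(names, bounds):
        ids = {bundle.proteins[j].id for j in order[start:stop]}
        prots = [p for p in bundle.proteins if p.id in ids]
        manifest = dict(bundle.manifest)
        manifest["split"] = name
        manifest["split_seed"] = seed
        out.append(
            Bundle(
                proteins=prots,
                sites=[s for s in bundle.sites if s.protein_id in ids],
                pssms={pid: bundle.pssms[pid] for pid in (p.id for p in prots)},
                structures={pid: bundle.structures[pid] for pid in (p.id for p in prots)},
                manifest=manifest,
            )
        )
        start = stop
    return out
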