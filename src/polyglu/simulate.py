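"""Synthetic MS1/MS2 data with the statistical structure the pipeline assumes.

The generator plants a known mixture of glutamylated peptidoforms for each
tubulin variant — a before-reaction pool (unmodified peptide) and an
after-reaction pool whose glutamylation states follow a truncated geometric
chain-length prior scaled by a planted conversion fraction — and emits:

* an MS1 table of envelope peaks (via the mass engine) scaled by abundance,
  with ppm-level m/z jitter and log-normal intensity noise;
* one MGF-style MS/MS peak list per modified precursor, with fragment ions
  present independently at a coverage probability, log-normal intensities,
  and uniform decoy peaks over the acquisition window;
* a ground-truth manifest echoing the config and every planted quantity.

Randomness is partitioned per spectrum (numpy seed sequences), so adding
spectra never perturbs earlier ones, and a fixed seed gives byte-identical
output files.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .digestion import DigestRule, cterm_peptide, digest
from .fragments import by_ladder
from .mass import composition, envelope, envelope_under_retention, mono_mass, mz as adduct_mz
from .matching import PeakList
from .tails import (
    Peptidoform,
    TailSequence,
    glu_chain,
    load_tails,
    make_variant,
)

__all__ = [
    "SimulationConfig",
    "SimulatedSample",
    "simulate_sample",
    "simulate_spectrum",
    "simulate_o18_envelope",
    "planted_state_distribution",
    "variant_cterm_peptidoform",
    "worked_example_fixtures",
    "ALPHA_BRANCH_SITES",
]

#: branch hotspots on the alpha-tubulin C-tail peptide
ALPHA_BRANCH_SITES = (445, 446, 447)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic experiment."""

    variants: tuple[str, ...] = ("TUBA1B:dTyr",)  # "isoform:variant_kind"
    max_k: int = 11  # longest chain simulated (alpha-scale default; up to 27 for beta)
    chain_p: float = 0.25  # truncated-geometric success prob over k = 1..max_k
    conversion: float = 0.9  # planted fraction of the after pool with k >= 1
    branch_fraction: float = 0.0  # share of modified signal in branched topology
    branch_sites: tuple[int, ...] = ()  # full-length residue numbers for branches
    label: str = "D5"
    isotopic_purity: float = 1.0
    coverage: float = 0.9  # per-fragment detection probability in MS/MS
    mz_sd_ppm: float = 5.0  # m/z jitter standard deviation
    intensity_sd: float = 0.1  # log-normal sigma on MS1 intensities
    frag_intensity_sd: float = 0.5  # log-normal sigma on fragment intensities
    decoy_peaks: int = 10  # uniform decoys per MS/MS spectrum
    window: tuple[float, float] = (250.0, 2500.0)  # acquisition window, m/z
    charges: tuple[int, ...] = (2, 3)
    charge_weights: tuple[float, ...] = (0.6, 0.4)
    total_intensity: float = 1e6  # per condition pool
    n_ms2: int | None = None  # cap on MS/MS spectra; None = every modified form
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("conversion", "branch_fraction", "coverage", "isotopic_purity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.chain_p < 1.0:
            raise ValueError("chain_p must be in (0, 1)")
        if self.branch_fraction > 0 and not self.branch_sites:
            raise ValueError("branch_fraction > 0 requires branch_sites")
        if len(self.charges) != len(self.charge_weights):
            raise ValueError("charges and charge_weights must align")


@dataclass
class SimulatedSample:
    manifest: dict
    ms1: pd.DataFrame  # columns: condition, variant, k, topology, mz, intensity
    spectra: list[PeakList]
    truth: dict[str, Peptidoform]  # spectrum source_id -> generating peptidoform
    candidates: dict[str, list[Peptidoform]]  # source_id -> isobaric candidate set


def planted_state_distribution(cfg: SimulationConfig) -> np.ndarray:
    """Planted probability of k = 0..max_k added glutamates in the after pool:
    P(0) = 1 - conversion; modified mass follows a truncated geometric."""
    k = np.arange(1, cfg.max_k + 1)
    geom = (1 - cfg.chain_p) ** (k - 1) * cfg.chain_p
    geom /= geom.sum()
    dist = np.concatenate([[1.0 - cfg.conversion], cfg.conversion * geom])
    return dist


def variant_cterm_peptidoform(
    isoform: str, kind: str, tails: Mapping[str, TailSequence] | None = None
) -> tuple[str, int]:
    """(peptide, full-length start) of the analyzed C-terminal peptide of a
    variant, using trypsin/LysC for alpha tails and AspN for beta tails."""
    tails = tails if tails is not None else load_tails()
    variant = make_variant(tails[isoform], kind)
    enzyme = "trypsin_lysC" if variant.base.chain_class == "alpha" else "aspN"
    peps = digest(variant.sequence, DigestRule(enzyme=enzyme))
    pep = cterm_peptide(peps)
    start = variant.numbering_offset + pep.start + 1
    return pep.sequence, start


def _topologies_for_state(
    peptide: str, start: int, k: int, cfg: SimulationConfig
) -> list[tuple[Peptidoform, float]]:
    """Planted (form, within-state share) pairs for state k."""
    if k == 0:
        return [(Peptidoform(peptide=peptide, start=start), 1.0)]
    out = []
    ext_share = 1.0 - cfg.branch_fraction
    if ext_share > 0:
        out.append(
            (
                Peptidoform(peptide=peptide, start=start, extension=glu_chain(k, cfg.label)),
                ext_share,
            )
        )
    if cfg.branch_fraction > 0:
        out.append(
            (
                Peptidoform(
                    peptide=peptide,
                    start=start,
                    branches=((cfg.branch_sites[0], glu_chain(k, cfg.label)),),
                ),
                cfg.branch_fraction,
            )
        )
    return out


def _ms1_rows(
    form: Peptidoform,
    abundance: float,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    condition: str,
    variant: str,
) -> list[dict]:
    env = envelope(composition(form), prune=1e-4)
    rows = []
    lo, hi = cfg.window
    for z, w in zip(cfg.charges, cfg.charge_weights):
        for m, a in env:
            target = adduct_mz(m, z, "protonated")
            if not lo <= target <= hi:
                continue
            jitter = rng.normal(0.0, cfg.mz_sd_ppm) * 1e-6 * target
            inten = (
                cfg.total_intensity
                * abundance
                * w
                * a
                * np.exp(rng.normal(0.0, cfg.intensity_sd))
            )
            rows.append(
                {
                    "condition": condition,
                    "variant": variant,
                    "k": form.total_added_glu,
                    "topology": form.topology(),
                    "mz": target + jitter,
                    "intensity": inten,
                }
            )
    return rows


def simulate_spectrum(
    form: Peptidoform,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    source_id: str,
    precursor_z: int = 2,
) -> PeakList:
    """One MS/MS peak list for a peptidoform under the config's noise model."""
    ladder = by_ladder(form, max_charge=max(1, min(2, precursor_z - 1)))
    mzs, intens = [], []
    for ion in ladder:
        if rng.random() > cfg.coverage:
            continue
        jitter = rng.normal(0.0, cfg.mz_sd_ppm) * 1e-6 * ion.mz
        mzs.append(ion.mz + jitter)
        intens.append(100.0 * np.exp(rng.normal(0.0, cfg.frag_intensity_sd)))
    lo, hi = cfg.window
    for _ in range(cfg.decoy_peaks):
        mzs.append(rng.uniform(lo, hi))
        intens.append(20.0 * np.exp(rng.normal(0.0, cfg.frag_intensity_sd)))
    return PeakList(
        precursor_mz=adduct_mz(mono_mass(composition(form)), precursor_z, "protonated"),
        precursor_z=precursor_z,
        mz=np.array(mzs),
        intensity=np.array(intens),
        source_id=source_id,
    )


def simulate_sample(cfg: SimulationConfig) -> SimulatedSample:
    """Draw a full synthetic experiment: MS1 table, MS/MS spectra, manifest."""
    tails = load_tails()
    for spec_id in cfg.variants:
        isoform, _, kind = spec_id.partition(":")
        if isoform not in tails:
            raise ValueError(f"unknown isoform {isoform!r}")
    dist = planted_state_distribution(cfg)
    ms1_rows: list[dict] = []
    spectra: list[PeakList] = []
    truth: dict[str, Peptidoform] = {}
    candidates: dict[str, list[Peptidoform]] = {}
    manifest: dict = {"config": asdict(cfg), "seed": cfg.seed, "variants": {}}
    spectrum_counter = 0
    for vi, spec_id in enumerate(cfg.variants):
        isoform, _, kind = spec_id.partition(":")
        peptide, start = variant_cterm_peptidoform(isoform, kind, tails)
        for pos in cfg.branch_sites:
            idx = pos - start
            if not (0 <= idx < len(peptide)) or peptide[idx] != "E":
                raise ValueError(f"branch site {pos} absent from peptide of {spec_id}")
        ms1_rng = np.random.default_rng([cfg.seed, 7, vi])
        # before pool: unmodified peptide only
        unmod = Peptidoform(peptide=peptide, start=start)
        ms1_rows += _ms1_rows(unmod, 1.0, cfg, ms1_rng, "before", spec_id)
        # after pool: planted state mixture
        planted_forms: list[tuple[Peptidoform, float]] = []
        for k, pk in enumerate(dist):
            for form, share in _topologies_for_state(peptide, start, k, cfg):
                planted_forms.append((form, pk * share))
                ms1_rows += _ms1_rows(form, pk * share, cfg, ms1_rng, "after", spec_id)
        # MS/MS for modified forms
        modified = [(f, a) for f, a in planted_forms if f.total_added_glu >= 1]
        if cfg.n_ms2 is not None:
            modified = modified[: cfg.n_ms2]
        for form, _ in modified:
            sid = f"sim|{spec_id}|{form.topology()}|k{form.total_added_glu}|{spectrum_counter}"
            rng = np.random.default_rng([cfg.seed, 11, spectrum_counter])
            spectra.append(simulate_spectrum(form, cfg, rng, sid))
            truth[sid] = form
            candidates[sid] = _isobaric_candidates(form, cfg)
            spectrum_counter += 1
        manifest["variants"][spec_id] = {
            "peptide": peptide,
            "start": start,
            "state_distribution": [float(p) for p in dist],
            "planted_forms": [
                {"form": f.canonical(), "abundance": float(a)} for f, a in planted_forms
            ],
        }
    ms1 = pd.DataFrame(ms1_rows)
    return SimulatedSample(
        manifest=manifest, ms1=ms1, spectra=spectra, truth=truth, candidates=candidates
    )


def _isobaric_candidates(form: Peptidoform, cfg: SimulationConfig) -> list[Peptidoform]:
    """The isobaric candidate set the analyst would weigh for this precursor:
    the extension form plus a same-length branch at every allowed site."""
    k = form.total_added_glu
    sites = cfg.branch_sites
    if not sites:
        # alpha default hotspots that actually lie on the peptide
        sites = tuple(
            pos
            for pos in ALPHA_BRANCH_SITES
            if form.start <= pos <= form.end and form.residue_at(pos) == "E"
        )
    cands = [
        Peptidoform(peptide=form.peptide, start=form.start, extension=glu_chain(k, cfg.label))
    ]
    for pos in sites:
        cands.append(
            Peptidoform(
                peptide=form.peptide,
                start=form.start,
                branches=((pos, glu_chain(k, cfg.label)),),
            )
        )
    return cands


def simulate_o18_envelope(
    p: Peptidoform,
    mode: str,
    rng: np.random.Generator,
    intensity_sd: float = 0.1,
    isotopic_purity: float = 1.0,
    prune: float = 1e-4,
) -> list[tuple[float, float]]:
    """Observed MS1 envelope of an 18O-labeled peptidoform under a linkage mode.

    ``alpha``: every label retained; ``gamma``: binomial(k-1, 1/2) labels lost
    across the within-chain isopeptide bonds.  Imperfect isotopic purity
    thins the label count binomially first.  Log-normal abundance noise is
    applied per peak and the envelope renormalized.
    """
    import math

    n = sum(1 for u in p.all_units if u.label == "O18")
    if n == 0:
        raise ValueError("peptidoform carries no 18O units")
    if mode not in ("alpha", "gamma"):
        raise ValueError(f"mode must be alpha or gamma, got {mode!r}")

    def binom(nn: int, pp: float) -> dict[int, float]:
        return {j: math.comb(nn, j) * pp**j * (1 - pp) ** (nn - j) for j in range(nn + 1)}

    labeled = binom(n, isotopic_purity) if isotopic_purity < 1.0 else {n: 1.0}
    retention: dict[int, float] = {}
    for lab, wl in labeled.items():
        if mode == "alpha" or lab < 2:
            retention[lab] = retention.get(lab, 0.0) + wl
        else:
            for lost, wg in binom(lab - 1, 0.5).items():
                retention[lab - lost] = retention.get(lab - lost, 0.0) + wl * wg
    theo = envelope_under_retention(p, retention, prune=prune)
    noisy = [(m, a * float(np.exp(rng.normal(0.0, intensity_sd)))) for m, a in theo]
    total = sum(a for _, a in noisy)
    return [(m, a / total) for m, a in noisy]


def worked_example_fixtures() -> dict[str, dict]:
    """Three noise-free exemplar spectra used in documentation and tests:
    an alpha-tail C-terminal extension, an alpha-tail lateral branch at E445,
    and a beta-tail extension."""
    noiseless = SimulationConfig(
        coverage=1.0, mz_sd_ppm=0.0, intensity_sd=0.0, frag_intensity_sd=0.0, decoy_peaks=0
    )
    tails = load_tails()
    out: dict[str, dict] = {}

    def build(name, isoform, kind, truth_builder, sites):
        peptide, start = variant_cterm_peptidoform(isoform, kind, tails)
        truth = truth_builder(peptide, start)
        k = truth.total_added_glu
        cands = [
            Peptidoform(peptide=peptide, start=start, extension=glu_chain(k, "D5"))
        ] + [
            Peptidoform(peptide=peptide, start=start, branches=((pos, glu_chain(k, "D5")),))
            for pos in sites
        ]
        rng = np.random.default_rng([2024, len(name)])
        spectrum = simulate_spectrum(truth, noiseless, rng, source_id=name)
        out[name] = {"spectrum": spectrum, "truth": truth, "candidates": cands}

    build(
        "alpha_extension",
        "TUBA1B",
        "dTyr",
        lambda pep, s: Peptidoform(peptide=pep, start=s, extension=glu_chain(2, "D5")),
        ALPHA_BRANCH_SITES,
    )
    build(
        "alpha_branch_E445",
        "TUBA1A",
        "Tyr",
        lambda pep, s: Peptidoform(peptide=pep, start=s, branches=((445, glu_chain(1, "D5")),)),
        ALPHA_BRANCH_SITES,
    )
    build(
        "beta_extension",
        "TUBB5",
        "native_beta",
        lambda pep, s: Peptidoform(peptide=pep, start=s, extension=glu_chain(3, "D5")),
        (),
    )
    return out
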