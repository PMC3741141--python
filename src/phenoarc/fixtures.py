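"""Seeded synthetic datasets emulating the two study shapes the tool is
aimed at, with a ground-truth manifest for every planted structure.

*Screen mode* emulates an imaging knockdown screen: per-time morphology
scores over seven default defect categories (mitotic delay, binuclear,
polylobed, grape, large, dynamic, apoptosis).  Planted transition motifs
make a block of genes switch their prominent phenotype from a source to a
target category at a chosen time; planted synchronous groups share an
entire succession template.  Background genes keep an unambiguous
prominent phenotype so the planted structure is exactly recoverable at
zero noise.

*Drug mode* emulates a time-course expression study: six treatment
conditions (nicotine, ethanol, cocaine, methamphetamine, heroin,
morphine) at four sampling times (1, 2, 4, 8 h), with designated gene
sets pushed into the lower or upper quartile of a condition's pooled
values at chosen times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataValueError
from .io import PhenoDataset

SCREEN_PHENOTYPES = [
    "mitotic_delay",
    "binuclear",
    "polylobed",
    "grape",
    "large",
    "dynamic",
    "apoptosis",
]

DRUG_CONDITIONS = [
    "nicotine",
    "ethanol",
    "cocaine",
    "methamphetamine",
    "heroin",
    "morphine",
]

#: sampling times of the drug time course, hours post injection
DRUG_HOURS = [1, 2, 4, 8]

#: scores used in screen mode at zero noise
PROMINENT_SCORE = 0.9
BACKGROUND_SCORE = 0.1


@dataclass(frozen=True)
class TransitionMotif:
    """``n_genes`` genes whose prominent phenotype switches
    ``source -> target`` between times ``t`` and ``t + 1``."""

    source: str
    target: str
    t: int
    n_genes: int


@dataclass(frozen=True)
class SyncGroup:
    """``size`` genes sharing the full succession ``template`` (a tuple of
    phenotype labels, one per time point)."""

    template: tuple[str, ...]
    size: int


@dataclass(frozen=True)
class QuartilePlant:
    """``n_genes`` genes pushed into the ``side`` ('lower'/'upper')
    quartile of each condition in ``conditions`` at time index ``t``."""

    conditions: tuple[str, ...]
    side: str
    t: int
    n_genes: int


@dataclass
class FixtureSpec:
    """Parameters of a synthetic dataset.

    ``background`` controls the profiles of unplanted genes in screen
    mode: ``"constant"`` gives each one a fixed prominent phenotype (no
    transitions), ``"distinct"`` gives every background gene a unique
    succession (no accidental synchrony).  The default ``"auto"`` picks
    ``"distinct"`` when synchronous groups are planted and ``"constant"``
    otherwise.
    """

    mode: str = "screen"
    n_genes: int = 30
    phenotypes: list[str] = field(default_factory=lambda: list(SCREEN_PHENOTYPES))
    n_timepoints: int = 10
    motifs: list[TransitionMotif] = field(default_factory=list)
    sync_groups: list[SyncGroup] = field(default_factory=list)
    quartile_plants: list[QuartilePlant] = field(default_factory=list)
    noise: float = 0.0
    seed: int = 0
    background: str = "auto"


@dataclass
class Manifest:
    """Ground truth of everything planted in a generated dataset."""

    transitions: list[tuple[str, str, int, int, frozenset[str]]] = field(default_factory=list)
    sync_cliques: list[frozenset[str]] = field(default_factory=list)
    quartile_members: list[tuple[str, str, int, frozenset[str]]] = field(default_factory=list)
    profiles: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def to_tsv(self) -> str:
        rows = ["kind\tdetail\tgenes"]
        for src, tgt, t0, t1, genes in self.transitions:
            rows.append(f"transition\t{src}>{tgt}@{t0}-{t1}\t{'|'.join(sorted(genes))}")
        for clique in self.sync_cliques:
            rows.append(f"sync_clique\tsize={len(clique)}\t{'|'.join(sorted(clique))}")
        for cond, side, t, genes in self.quartile_members:
            rows.append(f"quartile\t{cond}:{side}@{t}\t{'|'.join(sorted(genes))}")
        return "\n".join(rows) + "\n"


def generate(spec: FixtureSpec) -> tuple[PhenoDataset, Manifest]:
    """Build the dataset and its ground-truth manifest.

    Deterministic for a fixed ``spec.seed``; raises
    :class:`~phenoarc.errors.DataValueError` on infeasible plants
    (overlapping gene demand, out-of-range times, unknown labels).
    """
    if spec.mode == "screen":
        return _generate_screen(spec)
    if spec.mode == "drug":
        return _generate_drug(spec)
    raise DataValueError(f"unknown fixture mode {spec.mode!r}")


# ---------------------------------------------------------------------------
# screen mode


def _profile_from_motif(motif: TransitionMotif, n: int, phenotypes: list[str]) -> tuple[str, ...]:
    for lbl in (motif.source, motif.target):
        if lbl not in phenotypes:
            raise DataValueError(f"motif references unknown phenotype {lbl!r}")
    if not 0 <= motif.t < n - 1:
        raise DataValueError(f"motif time {motif.t} leaves no room for t+1")
    return tuple(
        motif.source if t <= motif.t else motif.target for t in range(n)
    )


def _unique_background_profile(j: int, n: int, phenotypes: list[str], used: set[tuple[str, ...]]) -> tuple[str, ...]:
    # enumerate profiles in mixed radix over phenotypes x times; skip used
    P = len(phenotypes)
    code = j
    while True:
        digits = []
        c = code
        for _ in range(n):
            digits.append(c % P)
            c //= P
        prof = tuple(phenotypes[d] for d in digits)
        if prof not in used:
            used.add(prof)
            return prof
        code += 1


def _generate_screen(spec: FixtureSpec) -> tuple[PhenoDataset, Manifest]:
    n, phen = spec.n_timepoints, list(spec.phenotypes)
    rng = np.random.default_rng(spec.seed)
    manifest = Manifest()

    profiles: dict[str, tuple[str, ...]] = {}
    used_templates: set[tuple[str, ...]] = set()
    cursor = 0

    def take(count: int) -> list[str]:
        nonlocal cursor
        if cursor + count > spec.n_genes:
            raise DataValueError(
                f"planted structures require more than the {spec.n_genes} "
                f"available genes"
            )
        genes = [f"g{cursor + i:03d}" for i in range(count)]
        cursor += count
        return genes

    for motif in spec.motifs:
        template = _profile_from_motif(motif, n, phen)
        genes = take(motif.n_genes)
        for g in genes:
            profiles[g] = template
        used_templates.add(template)
        manifest.transitions.append(
            (motif.source, motif.target, motif.t, motif.t + 1, frozenset(genes))
        )
        if motif.n_genes >= 2:
            manifest.sync_cliques.append(frozenset(genes))

    for group in spec.sync_groups:
        if len(group.template) != n:
            raise DataValueError(
                f"sync template length {len(group.template)} != {n} time points"
            )
        if group.template in used_templates:
            raise DataValueError("sync templates must be pairwise distinct")
        unknown = set(group.template) - set(phen)
        if unknown:
            raise DataValueError(f"sync template references unknown {sorted(unknown)}")
        genes = take(group.size)
        for g in genes:
            profiles[g] = group.template
        used_templates.add(group.template)
        if group.size >= 2:
            manifest.sync_cliques.append(frozenset(genes))

    background = spec.background
    if background == "auto":
        background = "distinct" if spec.sync_groups else "constant"
    n_background = spec.n_genes - cursor
    bg_genes = take(n_background)
    for j, g in enumerate(bg_genes):
        if background == "constant":
            profiles[g] = tuple([phen[j % len(phen)]] * n)
        elif background == "distinct":
            profiles[g] = _unique_background_profile(j, n, phen, used_templates)
        else:
            raise DataValueError(f"unknown background mode {background!r}")

    values: dict[tuple[str, str], np.ndarray] = {}
    genes = sorted(profiles)
    for g in genes:
        block = np.full((len(phen), n), BACKGROUND_SCORE)
        if spec.noise > 0:
            block = block + rng.normal(0.0, spec.noise, size=block.shape)
        for t, prominent in enumerate(profiles[g]):
            pi = phen.index(prominent)
            block[pi, t] = PROMINENT_SCORE + (
                rng.normal(0.0, spec.noise) if spec.noise > 0 else 0.0
            )
        for pi, p in enumerate(phen):
            values[(g, p)] = block[pi].copy()

    manifest.profiles = dict(profiles)
    dataset = PhenoDataset(genes, phen, n, values)
    return dataset, manifest


# ---------------------------------------------------------------------------
# drug mode


def _generate_drug(spec: FixtureSpec) -> tuple[PhenoDataset, Manifest]:
    conditions = (
        list(spec.phenotypes)
        if spec.phenotypes != SCREEN_PHENOTYPES
        else list(DRUG_CONDITIONS)
    )
    n = spec.n_timepoints if spec.n_timepoints != 10 else len(DRUG_HOURS)
    rng = np.random.default_rng(spec.seed)
    manifest = Manifest()
    genes = [f"g{i:03d}" for i in range(spec.n_genes)]

    # background expression ~ N(0, 1); plants sit far in the tails so the
    # pooled quartiles still fall inside the background bulk
    arr = rng.normal(0.0, 1.0, size=(spec.n_genes, len(conditions), n))
    cursor = 0
    for plant in spec.quartile_plants:
        if plant.side not in ("lower", "upper"):
            raise DataValueError(f"plant side must be lower/upper, got {plant.side!r}")
        if not 0 <= plant.t < n:
            raise DataValueError(f"plant time {plant.t} out of range")
        unknown = set(plant.conditions) - set(conditions)
        if unknown:
            raise DataValueError(f"plant references unknown conditions {sorted(unknown)}")
        if cursor + plant.n_genes > spec.n_genes:
            raise DataValueError("quartile plants require more genes than available")
        planted = genes[cursor : cursor + plant.n_genes]
        cursor += plant.n_genes
        level = -5.0 if plant.side == "lower" else 5.0
        for g in planted:
            gi = genes.index(g)
            for cond in plant.conditions:
                arr[gi, conditions.index(cond), plant.t] = level + rng.normal(
                    0.0, 0.1
                )
        for cond in plant.conditions:
            manifest.quartile_members.append(
                (cond, plant.side, plant.t, frozenset(planted))
            )

    values = {
        (g, cond): arr[gi, ci].copy()
        for gi, g in enumerate(genes)
        for ci, cond in enumerate(conditions)
    }
    dataset = PhenoDataset(genes, conditions, n, values)
    return dataset, manifest
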