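"""Synthetic interactome and expression generators with planted truth.

The score generator emulates an array-docking matrix: every cell is a grand
mean plus a drug (column) main effect, a pocket (row) main effect, an
optional sparse drug x pocket interaction, and Gaussian noise, with
missing-at-random gaps.  Two planted structures make the downstream
analyses testable end to end:

* an analog pair -- drug 2 is a copy of drug 1's effects except at a set of
  differential pockets, where drug 1 alone receives an extra interaction
  depth (negative depth = stronger binding of drug 1); the pair's noise is
  strongly correlated, emulating the near-identical docking profiles of
  ionization states or close analogs of one parent molecule;
* a case/control panel -- case drugs receive a binding boost (a negative
  score shift) at a set of mediator pockets.

The expression generator emulates a probe x instance fold-change compendium
with one planted, uniformly up-shifted gene set.  Every generator records
what it planted in a TruthRecord and is bit-reproducible under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cpi_data import (
    DrugRoster,
    GeneSet,
    PocketAnnotation,
    PocketRecord,
    ProbeGeneMap,
    ScoreMatrix,
)

__all__ = [
    "AnalogPairSpec",
    "CaseControlSpec",
    "CpiSimConfig",
    "TruthRecord",
    "simulate_cpi",
    "simulate_expression",
]


@dataclass(frozen=True)
class AnalogPairSpec:
    """Planted analog pair: drug2 mirrors drug1 except at the differential
    pockets, where ``depth`` is added to drug1's scores (negative depth =
    stronger theoretical binding of drug1).

    ``profile_correlation`` is the noise correlation between the two
    columns: analogs such as ionization states of one parent molecule dock
    near-identically, so their profiles correlate far above the background
    drug panel.
    """

    drug1: str = "ANALOG_1"
    drug2: str = "ANALOG_2"
    n_differential_pockets: int = 1
    depth: float = -5.0
    profile_correlation: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 <= self.profile_correlation <= 1.0):
            raise ValueError("profile_correlation must be in [0, 1]")


@dataclass(frozen=True)
class CaseControlSpec:
    """Planted case/control panel: ``boost`` (negative = stronger binding)
    is added to every case drug's score at each mediator pocket."""

    n_cases: int = 39
    n_controls: int = 15
    n_mediator_pockets: int = 5
    boost: float = -5.0


@dataclass(frozen=True)
class CpiSimConfig:
    """Generating model for a synthetic docking-score matrix.

    Defaults mirror the motivating study's dimensions: 255 drugs x 410
    pockets with 39 case and 15 control drugs.  Effect scales are in raw
    score units; ``missing_rate`` masks cells completely at random.
    """

    n_drugs: int = 255
    n_pockets: int = 410
    grand_mean: float = 0.0
    drug_sd: float = 1.0
    pocket_sd: float = 1.0
    noise_sd: float = 1.0
    interaction_sd: float = 0.0
    interaction_rate: float = 0.0
    missing_rate: float = 0.0
    analog_pair: AnalogPairSpec | None = None
    case_control: CaseControlSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_drugs < 2 or self.n_pockets < 2:
            raise ValueError("need at least 2 drugs and 2 pockets")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if not (0.0 <= self.interaction_rate <= 1.0):
            raise ValueError("interaction_rate must be in [0, 1]")
        for name in ("drug_sd", "pocket_sd", "noise_sd", "interaction_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        ap, cc = self.analog_pair, self.case_control
        if ap is not None and ap.n_differential_pockets > self.n_pockets:
            raise ValueError("more differential pockets than pockets")
        if cc is not None:
            if cc.n_mediator_pockets > self.n_pockets:
                raise ValueError("more mediator pockets than pockets")
            n_special = 2 if ap is not None else 0
            if cc.n_cases + cc.n_controls + n_special > self.n_drugs:
                raise ValueError("case + control (+ analog) drugs exceed n_drugs")


@dataclass(frozen=True)
class TruthRecord:
    """What a generator planted, for recovery tests."""

    differential_pockets: tuple[str, ...] = ()
    mediator_pockets: tuple[str, ...] = ()
    planted_gene_set: str | None = None
    variance_components: dict[str, float] = field(default_factory=dict)


def simulate_cpi(
    cfg: CpiSimConfig,
) -> tuple[ScoreMatrix, DrugRoster, PocketAnnotation, TruthRecord]:
    """Draw one synthetic score matrix plus roster, annotations and truth.

    score(i, j) = mu + drug_j + pocket_i + interaction(i, j) + eps(i, j).
    The analog partner copies drug1's main effect, interactions and planted
    depths except at the differential pockets; case drugs get the
    case/control boost at mediator pockets.  Bit-reproducible under
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    P, D = cfg.n_pockets, cfg.n_drugs

    drug_ids = [f"DRUG_{j:04d}" for j in range(D)]
    pocket_ids = [f"POCKET_{i:04d}" for i in range(P)]

    drug_eff = rng.normal(0.0, cfg.drug_sd, size=D) if cfg.drug_sd > 0 else np.zeros(D)
    pocket_eff = (
        rng.normal(0.0, cfg.pocket_sd, size=P) if cfg.pocket_sd > 0 else np.zeros(P)
    )
    inter = np.zeros((P, D))
    if cfg.interaction_sd > 0 and cfg.interaction_rate > 0:
        where = rng.random((P, D)) < cfg.interaction_rate
        inter[where] = rng.normal(0.0, cfg.interaction_sd, size=int(where.sum()))
    eps = rng.normal(0.0, cfg.noise_sd, size=(P, D)) if cfg.noise_sd > 0 else np.zeros((P, D))

    roles = {d: "background" for d in drug_ids}
    groups: dict[str, str] = {}
    diff_pockets: tuple[str, ...] = ()
    med_pockets: tuple[str, ...] = ()

    # reserve drug slots: analog pair first, then cases, then controls
    slot = 0
    if cfg.analog_pair is not None:
        ap = cfg.analog_pair
        j1, j2 = slot, slot + 1
        slot += 2
        drug_ids[j1], drug_ids[j2] = ap.drug1, ap.drug2
        roles.pop(f"DRUG_{j1:04d}"), roles.pop(f"DRUG_{j2:04d}")
        roles[ap.drug1] = roles[ap.drug2] = "background"
        groups[ap.drug1] = "parent1"
        groups[ap.drug2] = "parent2"
        drug_eff[j2] = drug_eff[j1]
        inter[:, j2] = inter[:, j1]
        rho = ap.profile_correlation
        eps[:, j2] = rho * eps[:, j1] + np.sqrt(1.0 - rho**2) * eps[:, j2]
        diff_idx = rng.choice(P, size=ap.n_differential_pockets, replace=False)
        inter[diff_idx, j1] += ap.depth
        diff_pockets = tuple(pocket_ids[i] for i in sorted(diff_idx))

    if cfg.case_control is not None:
        cc = cfg.case_control
        case_idx = list(range(slot, slot + cc.n_cases))
        ctrl_idx = list(range(slot + cc.n_cases, slot + cc.n_cases + cc.n_controls))
        for j in case_idx:
            roles[drug_ids[j]] = "case"
        for j in ctrl_idx:
            roles[drug_ids[j]] = "control"
        med_idx = rng.choice(P, size=cc.n_mediator_pockets, replace=False)
        inter[np.ix_(med_idx, case_idx)] += cc.boost
        med_pockets = tuple(pocket_ids[i] for i in sorted(med_idx))

    values = cfg.grand_mean + drug_eff[None, :] + pocket_eff[:, None] + inter + eps
    missing = rng.random((P, D)) < cfg.missing_rate
    m = ScoreMatrix(
        drug_ids=drug_ids, pocket_ids=pocket_ids, values=values, missing=missing
    )
    roster = DrugRoster(roles=roles, variant_groups=groups)
    records = {
        pid: PocketRecord(
            pocket_id=pid,
            pdb_id=f"PDB{i:04d}",
            gene_symbols=[f"GENE_{i:04d}"],
            classes=frozenset(
                (["DIFF"] if pid in diff_pockets else [])
                + (["MED"] if pid in med_pockets else [])
            ),
        )
        for i, pid in enumerate(pocket_ids)
    }
    annotations = PocketAnnotation(records=records)

    total = cfg.drug_sd**2 + cfg.pocket_sd**2 + cfg.noise_sd**2 + (
        cfg.interaction_rate * cfg.interaction_sd**2
    )
    vc = (
        {
            "drug": cfg.drug_sd**2 / total,
            "pocket": cfg.pocket_sd**2 / total,
            "residual": (cfg.noise_sd**2 + cfg.interaction_rate * cfg.interaction_sd**2)
            / total,
        }
        if total > 0
        else {}
    )
    truth = TruthRecord(
        differential_pockets=diff_pockets,
        mediator_pockets=med_pockets,
        variance_components=vc,
    )
    return m, roster, annotations, truth


def simulate_expression(
    n_genes: int,
    probes_per_gene: int | tuple[int, int] = 1,
    n_instances: int = 4,
    planted_size: int = 50,
    shift: float = 0.0,
    seed: int = 0,
    noise_sd: float = 1.0,
) -> tuple[np.ndarray, list[str], list[str], ProbeGeneMap, GeneSet, TruthRecord]:
    """Draw a probe x instance fold-change matrix with one up-shifted set.

    Fold changes are i.i.d. Gaussian noise; every probe of the planted
    genes is shifted by ``+shift`` in every instance (positive shift = up-
    regulated, hence smaller ranks).  ``probes_per_gene`` is a constant or
    an inclusive (low, high) range sampled per gene.  Returns
    (foldchange, probe_ids, instance_ids, probe_map, planted_set, truth).
    """
    if n_genes < 2 or n_instances < 1:
        raise ValueError("need >= 2 genes and >= 1 instance")
    if not (1 <= planted_size <= n_genes):
        raise ValueError(f"planted_size must be in [1, {n_genes}]")
    rng = np.random.default_rng(seed)
    genes = [f"GENE_{i:05d}" for i in range(n_genes)]
    if isinstance(probes_per_gene, int):
        counts = np.full(n_genes, probes_per_gene)
    else:
        lo, hi = probes_per_gene
        counts = rng.integers(lo, hi + 1, size=n_genes)
    if (counts < 1).any():
        raise ValueError("every gene needs at least one probe")
    probe_ids: list[str] = []
    probe_gene: dict[str, str] = {}
    for g, cnt in zip(genes, counts):
        for k in range(int(cnt)):
            pid = f"{g}_at{k}"
            probe_ids.append(pid)
            probe_gene[pid] = g
    instance_ids = [f"inst_{t}" for t in range(n_instances)]
    fc = rng.normal(0.0, noise_sd, size=(len(probe_ids), n_instances))
    planted = rng.choice(n_genes, size=planted_size, replace=False)
    planted_genes = frozenset(genes[i] for i in planted)
    planted_rows = [i for i, p in enumerate(probe_ids) if probe_gene[p] in planted_genes]
    fc[planted_rows, :] += shift
    gene_set = GeneSet(name="planted_up", genes=planted_genes)
    truth = TruthRecord(planted_gene_set="planted_up")
    return (
        fc,
        probe_ids,
        instance_ids,
        ProbeGeneMap(probe_to_gene=probe_gene),
        gene_set,
        truth,
    )
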