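"""Two-niche, multi-age synthetic single-cell count data with ground truth.

The generator emulates the structure of the cross-niche NSC study design:
two niches (V-SVZ, SGZ), five age groups from embryonic to adult, and three
cell types per niche (the RP/NSC lineage, niche astrocytes from the
perinatal stage onward, and proliferative TAPs/IPs at juvenile/adult ages).
Planted gene programs mirror the study's findings:

* a core RP/NSC identity shared by both niches (partially shared with
  astrocytes),
* an astrocyte program,
* a dormancy program whose effect ramps linearly with age in NSC-lineage
  cells, from 0 at the embryonic age to its configured maximum at the adult
  age, and which is absent from TAPs/IPs,
* niche-specific pallial (SGZ) and subpallial (V-SVZ) marker cohorts,
* proneurogenic programs — GABAergic genes in V-SVZ embryonic/perinatal
  precursors and TAPs, glutamatergic genes in the SGZ counterparts — both
  silent in dormant NSCs,
* a cell-cycle program in proliferative stages (embryonic/perinatal
  precursors and TAPs/IPs).

Counts are negative binomial with a gene-shared dispersion
(``var = mu + dispersion * mu^2``), multiplicative per-niche gene-wise
lognormal batch factors, and lognormal per-cell library-size factors.
Program genes draw their baseline means from a moderately-expressed
distribution (marker genes are detectably expressed); background genes
from a broader, lower one. Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import json

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .count_matrix import CellAnnotation, CountMatrix

__all__ = [
    "AgeGroup",
    "SyntheticConfig",
    "GroundTruth",
    "generate_dataset",
    "expected_contrast",
    "write_dataset",
]

NSC_LINEAGE = "NSC"
ASTROCYTE = "Astr"
PROGENITOR = "TAP/IP"


@dataclass(frozen=True)
class AgeGroup:
    name: str
    age_label: str
    age_days: int


DEFAULT_AGE_GROUPS: tuple[AgeGroup, ...] = (
    AgeGroup("embryonic", "E14.5", -5),
    AgeGroup("perinatal", "P0", 0),
    AgeGroup("early_postnatal", "P6", 6),
    AgeGroup("juvenile", "P20", 20),
    AgeGroup("adult", "P60", 60),
)

DEFAULT_PROGRAM_SIZES: Mapping[str, int] = {
    "core_identity": 79,
    "astrocyte": 26,
    "dormancy": 50,
    "pallial": 30,
    "subpallial": 30,
    "proneurogenic_gaba": 20,
    "proneurogenic_glut": 20,
    "cell_cycle": 100,
}

DEFAULT_EFFECTS: Mapping[str, float] = {name: 1.0 for name in DEFAULT_PROGRAM_SIZES}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic two-niche, multi-age design.

    Effect sizes are natural-log units applied multiplicatively to gene
    means. ``dispersion`` is the NB overdispersion (var = mu + d * mu^2).
    ``batch_sd`` is the SD of the per-niche gene-wise log batch factors and
    ``library_sigma`` the SD of the per-cell lognormal library factor.
    """

    seed: int = 0
    niches: tuple[str, str] = ("V-SVZ", "SGZ")
    age_groups: tuple[AgeGroup, ...] = DEFAULT_AGE_GROUPS
    cells_per_group: int = 200
    n_genes: int = 2000
    program_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PROGRAM_SIZES)
    )
    effects: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    dispersion: float = 0.1
    batch_sd: float = 0.1
    library_sigma: float = 0.3
    # lognormal parameters of baseline gene means (program vs background)
    program_base_logmean: float = 0.5
    program_base_logsd: float = 0.5
    background_base_logmean: float = -1.0
    background_base_logsd: float = 1.0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.cells_per_group < 1 or self.n_genes < 1:
            raise ValueError("cells_per_group and n_genes must be >= 1")
        if any(s < 0 for s in self.program_sizes.values()):
            raise ValueError("program sizes must be >= 0")
        if sum(self.program_sizes.values()) > self.n_genes:
            raise ValueError("program sizes exceed total gene count")
        if self.batch_sd < 0 or self.library_sigma < 0:
            raise ValueError("batch_sd and library_sigma must be >= 0")

    # -- serialization ------------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["age_groups"] = [list(a) for a in map(lambda g: (g.name, g.age_label, g.age_days), self.age_groups)]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "age_groups" in d:
            d["age_groups"] = tuple(AgeGroup(n, l, int(t)) for n, l, t in d["age_groups"])
        if "niches" in d:
            d["niches"] = tuple(d["niches"])
        return cls(**d)


def _cell_types_for(age: AgeGroup) -> list[str]:
    types = [NSC_LINEAGE]
    if age.age_days >= 0:
        types.append(ASTROCYTE)
    if age.name in ("juvenile", "adult"):
        types.append(PROGENITOR)
    return types


def _lineage_label(age: AgeGroup) -> str:
    return "RP" if age.age_days < 0 else "NSC"


def group_label(niche: str, age: AgeGroup, cell_type: str) -> str:
    display = _lineage_label(age) if cell_type == NSC_LINEAGE else cell_type
    return f"{niche} {age.age_label} {display}"


def _dormancy_ramp(age: AgeGroup, ages: Sequence[AgeGroup]) -> float:
    lo = min(a.age_days for a in ages)
    hi = max(a.age_days for a in ages)
    if hi == lo:
        return 1.0
    return float(np.clip((age.age_days - lo) / (hi - lo), 0.0, 1.0))


def program_activity(
    program: str, niche: str, age: AgeGroup, cell_type: str, config: SyntheticConfig
) -> float:
    """Fractional activity (0..1) of a program in one cell group."""
    proliferative_stage = age.name in ("embryonic", "perinatal")
    if program == "core_identity":
        if cell_type == NSC_LINEAGE:
            return 1.0
        if cell_type == ASTROCYTE:
            return 0.5  # astrocytes share part of the core identity
        return 0.0
    if program == "astrocyte":
        return 1.0 if cell_type == ASTROCYTE else 0.0
    if program == "dormancy":
        if cell_type != NSC_LINEAGE:
            return 0.0
        return _dormancy_ramp(age, config.age_groups)
    if program == "pallial":
        return 1.0 if niche == "SGZ" else 0.0
    if program == "subpallial":
        return 1.0 if niche == "V-SVZ" else 0.0
    if program == "proneurogenic_gaba":
        if niche != "V-SVZ":
            return 0.0
        return 1.0 if (cell_type == PROGENITOR or (cell_type == NSC_LINEAGE and proliferative_stage)) else 0.0
    if program == "proneurogenic_glut":
        if niche != "SGZ":
            return 0.0
        return 1.0 if (cell_type == PROGENITOR or (cell_type == NSC_LINEAGE and proliferative_stage)) else 0.0
    if program == "cell_cycle":
        return 1.0 if (cell_type == PROGENITOR or (cell_type == NSC_LINEAGE and proliferative_stage)) else 0.0
    raise KeyError(f"unknown program {program!r}")


@dataclass
class GroundTruth:
    """Planted programs, group effects, and expected contrast directions."""

    config: SyntheticConfig
    programs: dict[str, list[str]]
    genes: list[str]
    group_effects: pd.DataFrame  # groups x genes, total planted log-effect
    groups: list[str]

    def program_of(self, gene: str) -> str | None:
        for name, genes in self.programs.items():
            if gene in genes:
                return name
        return None

    def role_groups(self, niche: str) -> dict[str, list[str]]:
        """Group labels for the roles used in the dormant-signature contrasts."""
        cfg = self.config
        ages = {a.name: a for a in cfg.age_groups}
        emb = [group_label(niche, ages["embryonic"], NSC_LINEAGE)]
        dormant = [
            group_label(niche, ages[n], NSC_LINEAGE) for n in ("juvenile", "adult")
        ]
        taps = [group_label(niche, ages[n], PROGENITOR) for n in ("juvenile", "adult")]
        return {"embryonic_rp": emb, "dormant_nsc": dormant, "tap_ip": taps}

    def dormant_nsc_groups(self) -> list[str]:
        out: list[str] = []
        for niche in self.config.niches:
            out.extend(self.role_groups(niche)["dormant_nsc"])
        return out


def _assign_programs(config: SyntheticConfig, genes: list[str]) -> dict[str, list[str]]:
    programs: dict[str, list[str]] = {}
    cursor = 0
    for name, size in config.program_sizes.items():
        programs[name] = genes[cursor : cursor + size]
        cursor += size
    programs["background"] = genes[cursor:]
    return programs


def generate_dataset(
    config: SyntheticConfig | None = None,
) -> tuple[CountMatrix, CellAnnotation, GroundTruth]:
    """Simulate counts, annotation and ground truth from the configuration."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    genes = [f"g{i:04d}" for i in range(config.n_genes)]
    programs = _assign_programs(config, genes)

    n_program = sum(config.program_sizes.values())
    base = np.empty(config.n_genes)
    base[:n_program] = rng.lognormal(
        config.program_base_logmean, config.program_base_logsd, n_program
    )
    base[n_program:] = rng.lognormal(
        config.background_base_logmean,
        config.background_base_logsd,
        config.n_genes - n_program,
    )

    batch_log = {
        niche: rng.normal(0.0, config.batch_sd, config.n_genes)
        for niche in config.niches
    }

    gene_pos = {g: i for i, g in enumerate(genes)}
    program_rows = {
        name: np.array([gene_pos[g] for g in members], dtype=int)
        for name, members in programs.items()
        if name != "background"
    }

    blocks: list[sp.csr_matrix] = []
    cells: list[str] = []
    records: list[dict] = []
    group_effect_rows: dict[str, np.ndarray] = {}
    for niche in config.niches:
        for age in config.age_groups:
            for cell_type in _cell_types_for(age):
                label = group_label(niche, age, cell_type)
                effect = np.zeros(config.n_genes)
                for name, rows in program_rows.items():
                    act = program_activity(name, niche, age, cell_type, config)
                    if act:
                        effect[rows] += config.effects.get(name, 0.0) * act
                group_effect_rows[label] = effect

                mu = base * np.exp(effect + batch_log[niche])
                n = config.cells_per_group
                lib = rng.lognormal(0.0, config.library_sigma, n)
                mu_cells = mu[:, None] * lib[None, :]
                if config.dispersion > 0:
                    shape = 1.0 / config.dispersion
                    lam = rng.gamma(shape, mu_cells * config.dispersion)
                else:  # pragma: no cover - dispersion is validated > 0
                    lam = mu_cells
                counts = rng.poisson(lam)
                blocks.append(sp.csr_matrix(counts))

                safe = label.replace(" ", "_").replace("/", "-")
                ids = [f"{safe}_c{i:03d}" for i in range(n)]
                cells.extend(ids)
                for cid in ids:
                    records.append(
                        {
                            "cell": cid,
                            "niche": niche,
                            "age_label": age.age_label,
                            "age_days": age.age_days,
                            "group": label,
                            "batch": niche,
                        }
                    )

    mat = CountMatrix(genes=genes, cells=cells, counts=sp.hstack(blocks).tocsr())
    ann = CellAnnotation(pd.DataFrame.from_records(records).set_index("cell"))
    truth = GroundTruth(
        config=config,
        programs=programs,
        genes=genes,
        group_effects=pd.DataFrame.from_dict(
            group_effect_rows, orient="index", columns=genes
        ),
        groups=list(group_effect_rows),
    )
    return mat, ann, truth


def expected_contrast(
    gt: GroundTruth, contrast: tuple[str, str], tol: float = 1e-12
) -> pd.Series:
    """Expected DE direction ({up, down, null}) per gene for group1 vs group2.

    Directions come from the planted program effects only; batch and library
    factors are nuisance terms and do not enter.
    """
    g1, g2 = contrast
    for g in (g1, g2):
        if g not in gt.group_effects.index:
            raise KeyError(f"unknown group {g!r}; known: {gt.groups}")
    diff = gt.group_effects.loc[g1] - gt.group_effects.loc[g2]
    return pd.Series(
        np.select([diff > tol, diff < -tol], ["up", "down"], "null"),
        index=gt.group_effects.columns,
        name=f"{g1} vs {g2}",
    )


def write_dataset(
    mat: CountMatrix,
    ann: CellAnnotation,
    truth: GroundTruth | None,
    outdir: str | Path,
) -> None:
    """Write a 10x-style MTX triplet, metadata TSV and ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(outdir / "matrix.mtx", mat.counts.astype(int))
    (outdir / "genes.tsv").write_text("\n".join(mat.genes) + "\n")
    (outdir / "barcodes.tsv").write_text("\n".join(mat.cells) + "\n")
    ann.table.reset_index().rename(columns={"index": "cell"}).to_csv(
        outdir / "metadata.tsv", sep="\t", index=False
    )
    if truth is not None:
        payload = {
            "programs": truth.programs,
            "groups": truth.groups,
            "seed": truth.config.seed,
        }
        (outdir / "ground_truth.json").write_text(json.dumps(payload, indent=1))
        truth.config.to_yaml(outdir / "config.yaml")
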