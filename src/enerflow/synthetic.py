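"""Synthetic inputs: a toy metabolic network and a class-structured proteome.

The toy network is a desk-scale stand-in for a genome-scale human model.
It lumps central carbon metabolism into a handful of reactions chosen so
the maximum ATP flux has a closed form, while still exposing the
glycolysis <-> oxidative-phosphorylation trade-off that makes the supply
sweep non-trivial: glucose can be fermented to lactate (with proton
export) for a small ATP yield, or its pyruvate oxidised for a large one,
with oxygen as the shared limiting resource and glutamine as an optional
competing oxidative substrate.

The synthetic proteome draws per-class log-normal abundances (proteins in
the same functional class sit near a shared expression level, the
assumption the imputation exploits) and masks values with probabilities
stratified by tissue-expression category, mimicking LFQ missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import HPA_CATEGORIES, LOCALIZATIONS, AnnotationTable
from .gpr import parse_gpr
from .model import MetabolicModel, Reaction
from .proteome import ProteomeTable

__all__ = [
    "ToyModelSpec",
    "make_toy_model",
    "analytic_max_atp",
    "SyntheticProteomeSpec",
    "make_synthetic_proteome",
    "toy_bundle",
]

_INF = 1e6  # "open" bound; far above any flux the toy network can carry

#: Default gene-reaction rules for the toy network's internal reactions.
DEFAULT_GPR = {
    "GLCt": "Slc2a1 or Slc2a3",
    "GLYC": "Gapdh and Pkm",
    "LDH": "Ldha or Ldhb",
    "LACt": "Slc16a1",
    "OXPHOS": "(Ndufs1 and Sdha and Atp5f1a) or Atp5f1b",
    "GLNt": "Slc1a5",
    "GLNOX": "Gls and Glud1",
}


@dataclass
class ToyModelSpec:
    """Yields are mol ATP per mol substrate through the full (lumped) route.

    ``oxidative_atp_yield`` is the total per glucose when its pyruvate is
    fully oxidised (glycolytic part included); the oxidative step itself
    therefore yields (oxidative - glycolytic)/2 ATP per pyruvate.
    """

    n_carbon_sources: int = 1  # 1 = glucose; 2 adds glutamine
    glycolytic_atp_yield: float = 2.0
    oxidative_atp_yield: float = 32.0
    glutamine_atp_yield: float = 20.0
    o2_per_pyruvate: float = 3.0
    o2_per_glutamine: float = 3.0
    include_gtp_branch: bool = False
    gpr_templates: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_GPR))

    def __post_init__(self) -> None:
        if self.glycolytic_atp_yield <= 0 or self.oxidative_atp_yield <= 0:
            raise ValueError("ATP yields must be positive")
        if self.oxidative_atp_yield <= self.glycolytic_atp_yield:
            raise ValueError("oxidative yield must exceed glycolytic yield")
        if self.n_carbon_sources not in (1, 2):
            raise ValueError("n_carbon_sources must be 1 (glucose) or 2 (+glutamine)")
        for rxn_id, rule in self.gpr_templates.items():
            parse_gpr(rule)  # raises on malformed templates


def make_toy_model(
    spec: ToyModelSpec,
    glucose_bound: float = -10.0,
    oxygen_bound: float = -_INF,
    glutamine_bound: float = -10.0,
) -> MetabolicModel:
    """Build the toy network with an ATP-demand objective reaction.

    Exchange lower bounds default to glucose -10 with open oxygen.  The
    parameters of the closed-form maximum ATP flux are recorded in
    ``model.notes['analytic']`` (see :func:`analytic_max_atp`).
    """
    g = spec.glycolytic_atp_yield
    ox_per_pyr = (spec.oxidative_atp_yield - g) / 2.0
    gpr = spec.gpr_templates
    reactions = [
        Reaction("EX_glc_e", {"glc_e": -1}, glucose_bound, _INF, name="glucose exchange"),
        Reaction("EX_o2_e", {"o2_e": -1}, oxygen_bound, _INF, name="oxygen exchange"),
        Reaction("EX_lac_e", {"lac_e": -1}, 0.0, _INF, name="lactate exchange"),
        Reaction("EX_h_e", {"h_e": -1}, 0.0, _INF, name="proton exchange"),
        Reaction("GLCt", {"glc_e": -1, "glc_c": 1}, 0.0, _INF, gpr.get("GLCt", "")),
        Reaction("O2t", {"o2_e": -1, "o2_c": 1}, 0.0, _INF),
        Reaction(
            "GLYC",
            {"glc_c": -1, "pyr_c": 2, "atp_c": g},
            0.0,
            _INF,
            gpr.get("GLYC", ""),
            name="glycolysis (lumped)",
        ),
        Reaction(
            "LDH",
            {"pyr_c": -1, "lac_c": 1, "h_c": 1},
            0.0,
            _INF,
            gpr.get("LDH", ""),
            name="lactate fermentation",
        ),
        Reaction("LACt", {"lac_c": -1, "lac_e": 1}, 0.0, _INF, gpr.get("LACt", "")),
        Reaction("Ht", {"h_c": -1, "h_e": 1}, 0.0, _INF),
        Reaction(
            "OXPHOS",
            {"pyr_c": -1, "o2_c": -spec.o2_per_pyruvate, "atp_c": ox_per_pyr},
            0.0,
            _INF,
            gpr.get("OXPHOS", ""),
            name="pyruvate oxidation (lumped)",
        ),
        Reaction("ATPM", {"atp_c": -1}, 0.0, _INF, name="ATP demand"),
    ]
    if spec.n_carbon_sources >= 2:
        reactions += [
            Reaction("EX_gln_e", {"gln_e": -1}, glutamine_bound, _INF, name="glutamine exchange"),
            Reaction("GLNt", {"gln_e": -1, "gln_c": 1}, 0.0, _INF, gpr.get("GLNt", "")),
            Reaction(
                "GLNOX",
                {"gln_c": -1, "o2_c": -spec.o2_per_glutamine, "atp_c": spec.glutamine_atp_yield},
                0.0,
                _INF,
                gpr.get("GLNOX", ""),
                name="glutamine oxidation (lumped)",
            ),
        ]
    if spec.include_gtp_branch:
        reactions += [
            Reaction("NDPK", {"atp_c": -1, "gtp_c": 1}, 0.0, _INF, name="nucleoside diphosphate kinase"),
            Reaction("GTPM", {"gtp_c": -1}, 0.0, _INF, name="GTP demand"),
        ]
    model = MetabolicModel(
        id="toy_energy_model",
        reactions=reactions,
        objective_id="ATPM",
        name="toy central-carbon energy network",
        notes={
            "analytic": {
                "glycolytic_atp_yield": g,
                "oxidative_atp_per_pyruvate": ox_per_pyr,
                "glutamine_atp_yield": spec.glutamine_atp_yield if spec.n_carbon_sources >= 2 else 0.0,
                "o2_per_pyruvate": spec.o2_per_pyruvate,
                "o2_per_glutamine": spec.o2_per_glutamine,
            }
        },
    )
    return model


def analytic_max_atp(
    model: MetabolicModel,
    glucose_bound: float | None = None,
    oxygen_bound: float | None = None,
    glutamine_bound: float | None = None,
) -> float:
    """Closed-form maximum ATP flux of the toy network.

    Every imported glucose yields the glycolytic ATP; oxygen is then
    allocated greedily to the substrate with the higher ATP return per
    O2 (glutamine beats pyruvate at the default yields), and excess
    pyruvate leaves as lactate.  Bounds default to the model's current
    exchange bounds.
    """
    info = model.notes["analytic"]

    def _cap(rxn_id: str, override: float | None) -> float:
        if override is not None:
            return max(0.0, -override)
        try:
            return max(0.0, -model.reaction(rxn_id).lower_bound)
        except KeyError:
            return 0.0

    glc = _cap("EX_glc_e", glucose_bound)
    o2 = _cap("EX_o2_e", oxygen_bound)
    gln = _cap("EX_gln_e", glutamine_bound) if info["glutamine_atp_yield"] > 0 else 0.0

    substrates = [  # (ATP per unit, O2 per unit, capacity)
        (info["glutamine_atp_yield"], info["o2_per_glutamine"], gln),
        (info["oxidative_atp_per_pyruvate"], info["o2_per_pyruvate"], 2.0 * glc),
    ]
    substrates.sort(key=lambda t: t[0] / t[1], reverse=True)
    atp = info["glycolytic_atp_yield"] * glc
    for yield_atp, per_o2, cap in substrates:
        used = min(cap, o2 / per_o2)
        atp += yield_atp * used
        o2 -= used * per_o2
    return atp


# ---------------------------------------------------------------------------
# synthetic proteome
# ---------------------------------------------------------------------------

#: Tissue-expression category frequencies and per-category masking rates.
#: The masking rates average to ~20% overall missingness, typical of
#: label-free shotgun runs; "Not detected" proteins are absent by
#: definition (truth 0, always masked).
DEFAULT_CATEGORY_PROBS = {
    "Detected in all": 0.55,
    "Detected in many": 0.20,
    "Detected in some": 0.12,
    "Detected in single": 0.05,
    "Not detected": 0.02,
    "#N/A": 0.06,
}

DEFAULT_MISSING_FRAC = {
    "Detected in all": 0.10,
    "Detected in many": 0.25,
    "Detected in some": 0.35,
    "Detected in single": 0.50,
    "Not detected": 1.00,
    "#N/A": 0.30,
}


@dataclass
class SyntheticProteomeSpec:
    """Class-structured log-normal proteome with stratified masking.

    ``class_log_means`` are natural-log locations (defaults span
    ~1e4..1e7 intensity units); ``noise_sd`` is the within-class
    log-scale dispersion.  ``seed`` fixes the full output bit-for-bit.
    """

    n_classes: int = 20
    proteins_per_class: int = 50
    class_log_means: np.ndarray | None = None
    noise_sd: float = 0.8
    missing_frac_by_category: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSING_FRAC)
    )
    category_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROBS)
    )
    n_samples: int = 3
    class_names: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1 or self.proteins_per_class < 1:
            raise ValueError("need at least one class and one protein per class")
        for cat, frac in self.missing_frac_by_category.items():
            if cat not in HPA_CATEGORIES:
                raise ValueError(f"unknown tissue-expression category {cat!r}")
            if not 0.0 <= frac <= 1.0:
                raise ValueError("missing fractions must lie in [0, 1]")
        if self.class_log_means is None:
            self.class_log_means = np.linspace(np.log(1e4), np.log(1e7), self.n_classes)
        self.class_log_means = np.asarray(self.class_log_means, dtype=float)
        if self.class_log_means.size != self.n_classes:
            raise ValueError("class_log_means length must equal n_classes")
        if self.class_names is not None and len(self.class_names) != self.n_classes:
            raise ValueError("class_names length must equal n_classes")


def make_synthetic_proteome(
    spec: SyntheticProteomeSpec,
) -> tuple[ProteomeTable, ProteomeTable]:
    """Return (masked proteome, ground truth).

    Both tables carry identical metadata (class labels, localization,
    tissue-expression category); the masked table has NaN wherever a
    value was hidden, with per-category masking probabilities.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_classes * spec.proteins_per_class
    class_idx = np.repeat(np.arange(spec.n_classes), spec.proteins_per_class)
    class_names = spec.class_names or [f"C{i + 1:02d}" for i in range(spec.n_classes)]
    protein_ids = [
        f"{class_names[c]}_p{i % spec.proteins_per_class + 1:03d}".replace(" ", "_")
        for i, c in zip(range(n), class_idx)
    ]

    cats = list(spec.category_probs)
    probs = np.array([spec.category_probs[c] for c in cats], dtype=float)
    probs = probs / probs.sum()
    categories = rng.choice(cats, size=n, p=probs)

    sample_cols = [f"s{j + 1}" for j in range(spec.n_samples)]
    mu = spec.class_log_means[class_idx][:, None]
    log_abund = mu + rng.normal(0.0, spec.noise_sd, size=(n, spec.n_samples))
    truth_values = np.exp(log_abund)
    truth_values[categories == "Not detected", :] = 0.0

    mask_p = np.array([spec.missing_frac_by_category.get(c, 0.0) for c in categories])
    mask = rng.random(size=(n, spec.n_samples)) < mask_p[:, None]

    masked_values = truth_values.copy()
    masked_values[mask] = np.nan

    n_level2 = max(1, spec.n_classes // 3)
    meta = pd.DataFrame(
        {
            "class_level1": [class_names[c] for c in class_idx],
            "class_level2": [f"G{c % n_level2 + 1:02d}" for c in class_idx],
            "localization": [LOCALIZATIONS[c % len(LOCALIZATIONS)] for c in class_idx],
            "hpa_category": categories,
        },
        index=pd.Index(protein_ids, name="protein_id"),
    )
    data_index = pd.Index(protein_ids, name="protein_id")
    truth = ProteomeTable(pd.DataFrame(truth_values, index=data_index, columns=sample_cols), meta.copy())
    masked = ProteomeTable(pd.DataFrame(masked_values, index=data_index, columns=sample_cols), meta.copy())
    return masked, truth


# ---------------------------------------------------------------------------
# full input bundle for the end-to-end pipeline
# ---------------------------------------------------------------------------

#: Energy-ontology-style level-1 classes used by the bundle's demand side.
BUNDLE_CLASSES = [
    ("058_Nucleotide metabolism (ATP)", "JJ_Core metabolism nucleotides", "ATP"),
    ("011_Cytoskeleton (ATP)", "EE_Cytoskeleton", "ATP"),
    ("116_Glycosylation (ATP)", "MM_Protein turnover", "ATP"),
    ("096_Chaperone (ATP)", "MM_Protein turnover", "ATP"),
    ("084_Amino acid tRNA ligase (ATP)", "MM_Protein turnover", "ATP"),
    ("012_Cytoskeleton (GTP)", "EE_Cytoskeleton", "GTP"),
    ("107_Protein kinases (ATP)", "LL_Other metabolism&signaling", "ATP"),
    ("155_Ras GTPases (GTP)", "LL_Other metabolism&signaling", "GTP"),
    ("016_Glycolysis and Gluconeogenesis", "GG_Core metabolism carbohydrate", "none"),
    ("020_Citric acid and TCA cycle", "GG_Core metabolism carbohydrate", "none"),
    ("130_Ribosome structural", "MM_Protein turnover", "none"),
    ("001_Extracellular matrix", "AA_Extracellular matrix organization", "none"),
]

#: DMEM-like medium, mM (glucose reference 25); oxygen is unconstrained.
BUNDLE_MEDIUM = {"glc_e": 25.0, "gln_e": 4.0}

#: Measured exchange fluxes, pmol per ng protein per day (uptake negative),
#: and a Seahorse-style measured total ATP production rate in the same
#: units, in the range reported for fibroblast-like cells.
BUNDLE_MEASURED_FLUXES = {"glc_e": -15.0, "gln_e": -2.0, "lac_e": 25.0}
BUNDLE_MEASURED_ATP = 187.0
BUNDLE_MEASURED_GLUCOSE = 15.0


@dataclass
class ToyBundle:
    """Everything the pipeline consumes, generated from one seed."""

    model: MetabolicModel
    proteome: ProteomeTable
    truth: ProteomeTable
    annotation: AnnotationTable
    medium_mM: dict[str, float]
    measured_fluxes: dict[str, float]
    measured_atp: float
    measured_glucose: float


def write_bundle(bundle: ToyBundle, directory) -> dict[str, str]:
    """Write a bundle's inputs as the pipeline's on-disk formats.

    Returns a dict of logical name -> path (model JSON, proteome TSV,
    annotation TSV, medium TSV, measured-flux TSV).
    """
    from pathlib import Path

    from .model import write_json_model

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "model": directory / "toy_model.json",
        "proteome": directory / "proteome.tsv",
        "annotation": directory / "annotation.tsv",
        "medium": directory / "medium.tsv",
        "measured_fluxes": directory / "measured_fluxes.tsv",
    }
    write_json_model(bundle.model, paths["model"])
    bundle.proteome.to_tsv(paths["proteome"])
    bundle.annotation.to_tsv(paths["annotation"])
    pd.DataFrame(
        {"metabolite_id": list(bundle.medium_mM), "mM": list(bundle.medium_mM.values())}
    ).to_csv(paths["medium"], sep="\t", index=False)
    pd.DataFrame(
        {
            "condition": "WT",
            "metabolite_id": list(bundle.measured_fluxes),
            "flux": list(bundle.measured_fluxes.values()),
            "unit": "pmol/ng protein/day",
        }
    ).to_csv(paths["measured_fluxes"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}


def toy_bundle(
    seed: int = 0,
    proteins_per_class: int = 12,
    n_samples: int = 3,
    include_glutamine: bool = True,
) -> ToyBundle:
    """Generate a coherent toy model + proteome + annotation + measurements.

    The proteome covers the model's metabolic genes (always observed, so
    the supply side is fully determined) plus class-structured consumer
    proteins with ATP/GTP cofactor annotation; a handful of consumers
    carry kcat values so the kcat-weighting path is exercised.
    """
    rng = np.random.default_rng(seed)
    model_spec = ToyModelSpec(n_carbon_sources=2 if include_glutamine else 1)
    model = make_toy_model(model_spec)

    class_names = [name for name, _, _ in BUNDLE_CLASSES]
    prot_spec = SyntheticProteomeSpec(
        n_classes=len(BUNDLE_CLASSES),
        proteins_per_class=proteins_per_class,
        class_log_means=np.linspace(np.log(3e4), np.log(3e6), len(BUNDLE_CLASSES)),
        n_samples=n_samples,
        class_names=class_names,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    masked, truth = make_synthetic_proteome(prot_spec)

    # metabolic genes: always-observed abundances so supply bounds are exact
    genes = sorted(model.genes())
    gene_values = np.exp(rng.normal(np.log(5e5), 0.6, size=(len(genes), n_samples)))
    gene_index = pd.Index(genes, name="protein_id")
    gene_data = pd.DataFrame(gene_values, index=gene_index, columns=masked.samples)
    gene_meta = pd.DataFrame(
        {
            "class_level1": "016_Glycolysis and Gluconeogenesis",
            "class_level2": "GG_Core metabolism carbohydrate",
            "localization": "Cytosol",
            "hpa_category": "Detected in all",
        },
        index=gene_index,
    )
    proteome = ProteomeTable(
        pd.concat([masked.data, gene_data]), pd.concat([masked.meta, gene_meta])
    )
    truth_full = ProteomeTable(
        pd.concat([truth.data, gene_data]), pd.concat([truth.meta, gene_meta])
    )

    level2 = {name: lvl2 for name, lvl2, _ in BUNDLE_CLASSES}
    cofactor = {name: cof for name, _, cof in BUNDLE_CLASSES}
    ann_table = proteome.meta.copy()
    ann_table["function_level1"] = ann_table.pop("class_level1")
    ann_table["function_level2"] = ann_table["function_level1"].map(level2).fillna(
        "GG_Core metabolism carbohydrate"
    )
    ann_table["cofactor"] = ann_table["function_level1"].map(cofactor).fillna("none")
    # kcat known for ~40% of consumers, log-uniform 1..100 / s
    is_consumer = ann_table["cofactor"].isin(["ATP", "GTP"]).to_numpy()
    kcat = np.full(len(ann_table), np.nan)
    known = is_consumer & (rng.random(len(ann_table)) < 0.4)
    kcat[known] = 10 ** rng.uniform(0.0, 2.0, size=int(known.sum()))
    ann_table["kcat"] = kcat
    annotation = AnnotationTable(ann_table.rename_axis("gene_id"))

    medium = dict(BUNDLE_MEDIUM)
    measured = dict(BUNDLE_MEASURED_FLUXES)
    if not include_glutamine:
        medium.pop("gln_e", None)
        measured.pop("gln_e", None)
    return ToyBundle(
        model=model,
        proteome=proteome,
        truth=truth_full,
        annotation=annotation,
        medium_mM=medium,
        measured_fluxes=measured,
        measured_atp=BUNDLE_MEASURED_ATP,
        measured_glucose=BUNDLE_MEASURED_GLUCOSE,
    )
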