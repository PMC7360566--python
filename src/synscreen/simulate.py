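"""Synthetic drug-combination screens with known ground truth.

The generator emulates the screen design end to end: 3 colorectal-cancer
cell lines in planar (2D) and spheroid (3D) culture, a 7-drug panel screened
single-agent over 8 log-spaced doses (0.01-20 uM) and pairwise in 5x5 dose
matrices (vehicle + 4 nonzero doses per drug), 4 technical x 2 biological
replicates, per-plate vehicle and positive-control wells, and correlated
secondary readouts (confluency in 2D, spheroid size in 3D, cell-death
signals for apoptosis-inducing drugs).

Single-agent truth follows a Hill (4PL) curve per drug; combination truth is
Bliss-null viability V_A * V_B plus an injected additive deviation delta
(negative = synergy), so the ground-truth Bliss excess equals delta exactly
and pipeline recovery is an identity check.  Raw signals are the true
relative responses scaled to a plate baseline with multiplicative Gaussian
noise; everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .errors import DesignError
from .screen_model import (COLUMNS, ScreenDataset, enumerate_pairs, well_name)

__all__ = ["HillParams", "GeneratorConfig", "default_config", "simulate_screen",
           "truth_table", "config_to_yaml", "config_from_yaml"]


@dataclass(frozen=True)
class HillParams:
    """Ground-truth single-agent curve: V(d) = lower + (upper-lower)/(1+(d/ec50)^hill)."""

    upper: float = 1.0
    lower: float = 0.3
    ec50: float = 1.0  # uM
    hill: float = 1.0

    def viability(self, dose: float, ec50_scale: float = 1.0) -> float:
        if dose <= 0:
            return self.upper
        ec50 = self.ec50 * ec50_scale
        return self.lower + (self.upper - self.lower) / (1.0 + (dose / ec50) ** self.hill)


#: Per-drug Hill parameters echoing the observed potency ordering (the MEK
#: inhibitor PD most potent, then the TAK1 inhibitor 5Z; olaparib weakest).
_DEFAULT_PANEL = {
    "PD":   HillParams(upper=1.0, lower=0.15, ec50=0.05, hill=1.5),
    "5Z":   HillParams(upper=1.0, lower=0.20, ec50=0.30, hill=1.5),
    "PI":   HillParams(upper=1.0, lower=0.25, ec50=1.00, hill=1.2),
    "OXA":  HillParams(upper=1.0, lower=0.30, ec50=3.00, hill=1.0),
    "5-FU": HillParams(upper=1.0, lower=0.35, ec50=5.00, hill=1.0),
    "PAL":  HillParams(upper=1.0, lower=0.50, ec50=8.00, hill=1.0),
    "OLA":  HillParams(upper=1.0, lower=0.60, ec50=15.0, hill=0.8),
}

#: Context-specific potency shifts (EC50 multipliers): HT-29 less sensitive
#: to oxaliplatin and palbociclib in 3D, HCT-116 more sensitive to MEK
#: inhibition in 3D.
_DEFAULT_EC50_SCALE = {
    ("OXA", "HT-29", "3D"): 3.0,
    ("PAL", "HT-29", "3D"): 3.0,
    ("PD", "HCT-116", "3D"): 0.4,
}

#: Injected Bliss deviations (delta, viability scale; negative = synergy).
#: Keys are (drug_a, drug_b) for all contexts or (drug_a, drug_b, cell_line,
#: culture_format); pair members lexicographic.  The default map gives six
#: interacting pairs with |delta| <= 0.2, synergy of the MEK-inhibitor pairs
#: stronger in 3D.
_DEFAULT_INTERACTIONS = {
    ("PD", "PI"): -0.15,
    ("5Z", "PI"): -0.12,
    ("OXA", "PD", "HCT-116", "3D"): -0.15,
    ("OXA", "PD", "HT-29", "3D"): -0.10,
    ("5-FU", "OXA"): -0.08,
    ("PAL", "PD"): -0.08,
    ("5-FU", "OLA", "HCT-116", "3D"): -0.10,
    ("5-FU", "OLA", "SW-620", "3D"): -0.10,
    ("OLA", "PAL"): 0.06,  # one antagonistic pair
}

_READOUTS_BY_FORMAT = {"2D": ("viability", "confluency"),
                       "3D": ("viability", "spheroid_size")}
_SINGLE_READOUTS_BY_FORMAT = {"2D": ("viability", "confluency", "celltox", "nucview"),
                              "3D": ("viability", "spheroid_size")}

#: Raw-signal baselines per readout (vehicle level, arbitrary units).  The
#: luminescence baseline is a power of two so that scaling to raw counts and
#: back through vehicle normalization is exact in floating point: at zero
#: noise the pipeline then recovers true viabilities bit-for-bit and the
#: Bliss null scores exactly 0.
_BASELINES = {"viability": float(2 ** 20), "confluency": 80.0,
              "spheroid_size": 400.0, "celltox": 1000.0, "nucview": 1000.0}


@dataclass
class GeneratorConfig:
    """Full specification of a synthetic screen; deterministic given ``seed``."""

    cell_lines: tuple = ("HCT-116", "HT-29", "SW-620")
    formats: tuple = ("2D", "3D")
    drugs: dict = field(default_factory=lambda: dict(_DEFAULT_PANEL))
    ec50_scale: dict = field(default_factory=lambda: dict(_DEFAULT_EC50_SCALE))
    interactions: dict = field(default_factory=lambda: dict(_DEFAULT_INTERACTIONS))
    single_doses: tuple = tuple(np.geomspace(0.01, 20.0, 8).round(4))
    n_combo_doses: int = 4
    combo_dose_overrides: dict = field(default_factory=dict)  # drug -> doses
    n_tech: int = 4
    n_bio: int = 2
    noise_sd: dict = field(default_factory=lambda: {"2D": 0.05, "3D": 0.07})
    vehicle_signal: float = _BASELINES["viability"]
    n_vehicle_wells: int = 16
    n_positive_wells: int = 8
    confluency_exponent: float = 0.8
    size_exponent: float = 1.0 / 3.0
    death_gain: float = 4.0
    apoptosis_flags: tuple = ("5Z",)
    include_single_screen: bool = True
    readouts: tuple | None = None  # override: restrict every screen to these
    excluded: tuple = ()  # (drug_a, dose_a, drug_b, dose_b, bio_rep) wells to drop
    timepoint: float = 48.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tech < 1 or self.n_bio < 1:
            raise DesignError("replicate counts must be >= 1 (n_tech/n_bio)")
        if any(d <= 0 for d in self.single_doses):
            raise DesignError("single_doses must be positive")
        for fmt, sd in self.noise_sd.items():
            if sd < 0:
                raise DesignError(f"noise_sd must be >= 0 (format {fmt})")
        for name, hp in self.drugs.items():
            if not (0 <= hp.lower <= hp.upper):
                raise DesignError(f"drugs[{name}]: need 0 <= lower <= upper")
            if hp.ec50 <= 0 or hp.hill <= 0:
                raise DesignError(f"drugs[{name}]: ec50 and hill must be positive")
        if len(self.drugs) < 2:
            raise DesignError("drugs: need a panel of at least 2")

    # -- ground truth ------------------------------------------------------
    def context_ec50_scale(self, drug: str, cell_line: str, fmt: str) -> float:
        return self.ec50_scale.get((drug, cell_line, fmt), 1.0)

    def true_viability(self, drug: str, dose: float, cell_line: str, fmt: str) -> float:
        return self.drugs[drug].viability(
            dose, self.context_ec50_scale(drug, cell_line, fmt))

    def delta(self, drug_a: str, drug_b: str, cell_line: str, fmt: str) -> float:
        a, b = sorted((drug_a, drug_b))
        if (a, b, cell_line, fmt) in self.interactions:
            return self.interactions[(a, b, cell_line, fmt)]
        return self.interactions.get((a, b), 0.0)

    def combo_doses(self, drug: str, cell_line: str, fmt: str) -> tuple:
        """The 4 matrix doses for a drug: the window of consecutive screen
        doses whose log-center best brackets the drug's contextual EC50."""
        if drug in self.combo_dose_overrides:
            return tuple(self.combo_dose_overrides[drug])
        doses = np.asarray(self.single_doses)
        k = self.n_combo_doses
        ec50 = self.drugs[drug].ec50 * self.context_ec50_scale(drug, cell_line, fmt)
        centers = [np.log10(doses[i:i + k]).mean() for i in range(len(doses) - k + 1)]
        start = int(np.argmin(np.abs(np.array(centers) - np.log10(ec50))))
        return tuple(doses[start:start + k])

    def screen_readouts(self, fmt: str, screen: str) -> tuple:
        table = _READOUTS_BY_FORMAT if screen == "combination" else _SINGLE_READOUTS_BY_FORMAT
        readouts = table[fmt]
        if self.readouts is not None:
            readouts = tuple(r for r in readouts if r in self.readouts)
        return readouts


def default_config(**overrides) -> GeneratorConfig:
    """The standard screen design; keyword overrides are applied on top."""
    return replace(GeneratorConfig(), **overrides) if overrides else GeneratorConfig()


class _PlateAllocator:
    """Sequential well/plate allocation; each plate reserves control wells."""

    CAPACITY = 384

    def __init__(self, prefix: str, n_vehicle: int, n_positive: int):
        self.prefix = prefix
        self.n_vehicle = n_vehicle
        self.n_positive = n_positive
        self.plate_no = 0
        self.cursor = self.CAPACITY  # force a new plate on first use
        self.controls: list[tuple[str, str, str]] = []  # (plate, well, role)

    def _new_plate(self) -> None:
        self.plate_no += 1
        self.cursor = 0
        plate = self.plate_id
        for _ in range(self.n_vehicle):
            self.controls.append((plate, self._take(), "vehicle"))
        for _ in range(self.n_positive):
            self.controls.append((plate, self._take(), "positive_control"))

    @property
    def plate_id(self) -> str:
        return f"{self.prefix}-p{self.plate_no}"

    def _take(self) -> str:
        w = well_name(self.cursor // 24, self.cursor % 24)
        self.cursor += 1
        return w

    def take_treatment(self) -> tuple[str, str]:
        if self.cursor >= self.CAPACITY:
            self._new_plate()
        return self.plate_id, self._take()


def _readout_raw(readout: str, v: float, effect_death: float, config) -> float:
    """Map a true relative viability to the raw-signal scale of a readout."""
    base = config.vehicle_signal if readout == "viability" else _BASELINES[readout]
    if readout == "viability":
        return base * v
    if readout == "confluency":
        return base * max(v, 0.0) ** config.confluency_exponent
    if readout == "spheroid_size":
        return base * max(v, 0.0) ** config.size_exponent
    # death readouts: near-baseline unless the treatment is apoptotic
    return base * (1.0 + config.death_gain * effect_death)


def simulate_screen(config: GeneratorConfig) -> ScreenDataset:
    """Generate the raw per-well dataset for a configured screen."""
    rng = np.random.default_rng(config.seed)
    rows: list[tuple] = []
    excluded = {tuple(e) for e in config.excluded}

    def emit(plate, well, cell, fmt, role, da, xa, db, xb, readouts, v, edeath,
             tech, bio):
        sd = config.noise_sd[fmt]
        for readout in readouts:
            raw = _readout_raw(readout, v, edeath, config)
            noisy = max(raw * (1.0 + rng.normal(0.0, sd)), 0.0) if sd > 0 else raw
            rows.append((plate, well, cell, fmt, role, da, xa, db, xb,
                         readout, config.timepoint, tech, bio, noisy))

    pairs = enumerate_pairs(sorted(config.drugs))
    for cell in config.cell_lines:
        for fmt in config.formats:
            readouts_c = config.screen_readouts(fmt, "combination")
            for bio in range(1, config.n_bio + 1):
                alloc = _PlateAllocator(f"C-{cell}-{fmt}-b{bio}",
                                        config.n_vehicle_wells,
                                        config.n_positive_wells)
                for a, b in pairs:
                    doses_a = (0.0,) + config.combo_doses(a, cell, fmt)
                    doses_b = (0.0,) + config.combo_doses(b, cell, fmt)
                    delta = config.delta(a, b, cell, fmt)
                    for xa in doses_a:
                        for xb in doses_b:
                            if xa == 0.0 and xb == 0.0:
                                continue
                            if (a, xa, b, xb, bio) in excluded:
                                continue
                            va = config.true_viability(a, xa, cell, fmt)
                            vb = config.true_viability(b, xb, cell, fmt)
                            if xa > 0 and xb > 0:
                                v = float(np.clip(va * vb + delta, 0.0, 1.5))
                            else:
                                v = va if xa > 0 else vb
                            apo = ((xa > 0 and a in config.apoptosis_flags)
                                   or (xb > 0 and b in config.apoptosis_flags))
                            edeath = (1.0 - min(v, 1.0)) if apo else 0.0
                            for tech in range(1, config.n_tech + 1):
                                plate, well = alloc.take_treatment()
                                emit(plate, well, cell, fmt, "treatment",
                                     a, xa, b, xb, readouts_c, v, edeath, tech, bio)
                for plate, well, role in alloc.controls:
                    v = 1.0 if role == "vehicle" else 0.05
                    da = "" if role == "vehicle" else "STS"
                    xa = 0.0 if role == "vehicle" else 1.0
                    emit(plate, well, cell, fmt, role, da, xa, "", 0.0,
                         readouts_c, v, 0.0, 1, bio)

            if config.include_single_screen:
                readouts_s = config.screen_readouts(fmt, "single")
                alloc = _PlateAllocator(f"S-{cell}-{fmt}-b1",
                                        config.n_vehicle_wells,
                                        config.n_positive_wells)
                for drug in sorted(config.drugs):
                    apo_drug = drug in config.apoptosis_flags
                    for dose in config.single_doses:
                        v = config.true_viability(drug, dose, cell, fmt)
                        edeath = (1.0 - min(v, 1.0)) if apo_drug else 0.0
                        for tech in range(1, config.n_tech + 1):
                            plate, well = alloc.take_treatment()
                            emit(plate, well, cell, fmt, "treatment",
                                 drug, dose, "", 0.0, readouts_s, v, edeath, tech, 1)
                for plate, well, role in alloc.controls:
                    v = 1.0 if role == "vehicle" else 0.05
                    da = "" if role == "vehicle" else "STS"
                    xa = 0.0 if role == "vehicle" else 1.0
                    emit(plate, well, cell, fmt, role, da, xa, "", 0.0,
                         readouts_s, v, 0.0, 1, 1)

    df = pd.DataFrame(rows, columns=list(COLUMNS))
    return ScreenDataset(df)


def truth_table(config: GeneratorConfig) -> pd.DataFrame:
    """Closed-form ground-truth expectations per (cell line, format, pair).

    Computed from the Hill parameters and the interaction map with no
    sampling: the injected delta, the true mean Bliss excess over the 16
    combination cells (after clipping combined viability to [0, 1.5]), the
    true mean combination viability, the synergy flag and the number of
    synergistically effective dose pairs at zero noise.
    """
    pairs = enumerate_pairs(sorted(config.drugs))
    out = []
    for cell in config.cell_lines:
        for fmt in config.formats:
            for a, b in pairs:
                delta = config.delta(a, b, cell, fmt)
                va = np.array([config.true_viability(a, d, cell, fmt)
                               for d in config.combo_doses(a, cell, fmt)])
                vb = np.array([config.true_viability(b, d, cell, fmt)
                               for d in config.combo_doses(b, cell, fmt)])
                null = np.outer(va, vb)
                vobs = np.clip(null + delta, 0.0, 1.5)
                excess = vobs - null
                n_eff = int(np.sum((excess < 0.0) & (vobs <= 0.5)))
                mean_excess = float(excess.mean())
                out.append({
                    "cell_line": cell, "culture_format": fmt,
                    "drug_a": a, "drug_b": b, "delta": delta,
                    "true_mean_excess": mean_excess,
                    "true_mean_viability": float(vobs.mean()),
                    "synergistic": bool(mean_excess < 0.0),
                    "n_effective": n_eff,
                })
    return pd.DataFrame(out)


# -- YAML round-trip --------------------------------------------------------

def config_to_yaml(config: GeneratorConfig, path) -> None:
    doc = {
        "cell_lines": list(config.cell_lines),
        "formats": list(config.formats),
        "drugs": {name: vars(hp).copy() for name, hp in config.drugs.items()},
        "ec50_scale": [{"drug": d, "cell_line": c, "culture_format": f, "scale": s}
                       for (d, c, f), s in config.ec50_scale.items()],
        "interactions": [
            {"drug_a": k[0], "drug_b": k[1], "delta": v,
             **({"cell_line": k[2], "culture_format": k[3]} if len(k) == 4 else {})}
            for k, v in config.interactions.items()],
        "single_doses": [float(d) for d in config.single_doses],
        "n_combo_doses": config.n_combo_doses,
        "combo_dose_overrides": {d: [float(x) for x in v]
                                 for d, v in config.combo_dose_overrides.items()},
        "n_tech": config.n_tech, "n_bio": config.n_bio,
        "noise_sd": dict(config.noise_sd),
        "vehicle_signal": config.vehicle_signal,
        "n_vehicle_wells": config.n_vehicle_wells,
        "n_positive_wells": config.n_positive_wells,
        "confluency_exponent": config.confluency_exponent,
        "size_exponent": config.size_exponent,
        "death_gain": config.death_gain,
        "apoptosis_flags": list(config.apoptosis_flags),
        "include_single_screen": config.include_single_screen,
        "readouts": list(config.readouts) if config.readouts is not None else None,
        "excluded": [list(e) for e in config.excluded],
        "timepoint": config.timepoint,
        "seed": config.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def config_from_yaml(path) -> GeneratorConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    kwargs = dict(doc)
    kwargs["cell_lines"] = tuple(doc.get("cell_lines", GeneratorConfig.cell_lines))
    kwargs["formats"] = tuple(doc.get("formats", GeneratorConfig.formats))
    kwargs["drugs"] = {name: HillParams(**hp) for name, hp in doc["drugs"].items()}
    kwargs["ec50_scale"] = {(e["drug"], e["cell_line"], e["culture_format"]): e["scale"]
                            for e in doc.get("ec50_scale", [])}
    inter = {}
    for e in doc.get("interactions", []):
        key = tuple(sorted((e["drug_a"], e["drug_b"])))
        if "cell_line" in e:
            key = key + (e["cell_line"], e["culture_format"])
        inter[key] = e["delta"]
    kwargs["interactions"] = inter
    kwargs["single_doses"] = tuple(doc["single_doses"])
    kwargs["combo_dose_overrides"] = {d: tuple(v) for d, v in
                                      doc.get("combo_dose_overrides", {}).items()}
    kwargs["apoptosis_flags"] = tuple(doc.get("apoptosis_flags", ()))
    if doc.get("readouts") is not None:
        kwargs["readouts"] = tuple(doc["readouts"])
    else:
        kwargs["readouts"] = None
    kwargs["excluded"] = tuple(tuple(e) for e in doc.get("excluded", ()))
    return GeneratorConfig(**kwargs)
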