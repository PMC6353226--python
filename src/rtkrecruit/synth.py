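"""Synthetic inputs with the statistical structure of the real data.

Quantitative proteomics panels report copy numbers spanning roughly
10^2-10^7 per cell, and SH2/PTB-phosphosite interactions have K_D values
of order 0.1-10 uM over a sparse bipartite map of up to 18 proteins and
six receptor tyrosines.  The generators here emulate those features with
seeded, reproducible draws, and the table readers/writers speak the
tab-separated layouts used for per-line copy-number tables and per-edge
K_D tables.

``hela_like_fixture`` transcribes the qualitative facts known about the
HeLa S3 background (which proteins bind which site, which are absent, the
relative abundances and affinity ratios) into one concrete profile + map.
It is a synthetic stand-in, not a measured dataset, so checks
built on it are qualitative: orderings and correlation signs, not dataset-specific
quantitative values.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .cell_model import CellProfile, InteractionMap, RECEPTOR, DEFAULT_SITES

__all__ = [
    "SyntheticSpec",
    "PARTNER_ROSTER",
    "generate_cell_profile",
    "generate_interaction_map",
    "generate_cell_panel",
    "hela_like_fixture",
    "full_scale_interaction_map",
    "write_profile_tsv",
    "read_profile_tsv",
    "write_map_tsv",
    "read_map_tsv",
    "read_supplementary_tables",
    "write_sidecar",
]

#: 18 SH2/PTB-domain proteins used as the synthetic partner roster.
PARTNER_ROSTER = (
    "ABL2", "BLK", "CRK", "CRKL", "IRS1", "ITK", "PIK3R1", "PIK3R2",
    "PIK3R3", "PLCG2", "RASA1", "SHC1", "SRC", "STAT1", "SYK", "VAV2",
    "YES1", "ZAP70",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic generators (all draws are seeded)."""

    seed: int = 0
    n_proteins: int = 18
    n_sites: int = 6
    abundance_range: tuple = (1e2, 1e7)      # copies/cell, log-uniform
    receptor_range: tuple = (5e3, 5e4)       # IGF1R copies (nM-range receptor)
    kd_range: tuple = (1e-7, 1e-5)           # molar, log-uniform
    edge_density: float = 0.5
    n_edges: int = None                      # overrides density when set
    proteins: tuple = None
    sites: tuple = None

    def __post_init__(self):
        if not 1 <= self.n_proteins <= len(PARTNER_ROSTER):
            raise ValueError(f"n_proteins must be in 1..{len(PARTNER_ROSTER)}")
        if not 0 < self.edge_density <= 1:
            raise ValueError("edge density must be in (0, 1]")
        for lo, hi in (self.abundance_range, self.kd_range, self.receptor_range):
            if not 0 < lo <= hi:
                raise ValueError("ranges must be positive and ordered")
        if self.proteins is None:
            object.__setattr__(self, "proteins", PARTNER_ROSTER[: self.n_proteins])
        if self.sites is None:
            object.__setattr__(self, "sites", DEFAULT_SITES[: self.n_sites])


def _log_uniform(rng, lo, hi, size=None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def generate_cell_profile(spec: SyntheticSpec, name: str = "SYNTH",
                          zero_mask=()) -> CellProfile:
    """Seeded log-uniform copy-number profile; masked proteins are set to 0."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.abundance_range
    copies = {p: float(c) for p, c in
              zip(spec.proteins, _log_uniform(rng, lo, hi, len(spec.proteins)))}
    copies[RECEPTOR] = float(_log_uniform(rng, *spec.receptor_range))
    for p in zero_mask:
        if p in copies and p != RECEPTOR:
            copies[p] = 0.0
    return CellProfile(name=name, copies=copies)


def generate_interaction_map(spec: SyntheticSpec) -> InteractionMap:
    """Seeded bipartite protein-site map; every site gets >= 1 partner."""
    rng = np.random.default_rng(spec.seed + 1)
    pairs = [(p, s) for s in spec.sites for p in spec.proteins]
    if spec.n_edges is not None:
        if spec.n_edges < spec.n_sites or spec.n_edges > len(pairs):
            raise ValueError("n_edges incompatible with site coverage")
        chosen = {(spec.proteins[rng.integers(len(spec.proteins))], s)
                  for s in spec.sites}
        rest = [pq for pq in pairs if pq not in chosen]
        extra = rng.choice(len(rest), size=spec.n_edges - len(chosen),
                           replace=False)
        chosen |= {rest[i] for i in extra}
    else:
        keep = rng.random(len(pairs)) < spec.edge_density
        chosen = {pq for pq, k in zip(pairs, keep) if k}
        if any(all((p, s) not in chosen for p in spec.proteins)
               for s in spec.sites):
            raise ValueError(
                "edge density too low: a site was left without partners"
            )
    lo, hi = spec.kd_range
    edges = tuple(
        (p, s, float(_log_uniform(rng, lo, hi)))
        for p, s in sorted(chosen)
    )
    return InteractionMap.from_edges(edges)


def generate_cell_panel(base: CellProfile, n_lines: int, seed: int = 0,
                        sigma_ln: float = 1.5, dropout: float = 0.12,
                        tissues=("OVAR", "NSCLC", "MELAN", "CERV", "CNS",
                                 "LEUK", "BREAST", "COLON", "RENAL", "PROST")
                        ) -> list:
    """Panel of cell-line profiles: lognormal spread around a base profile.

    Protein abundances across cell lines commonly vary by one to two orders
    of magnitude, so each copy number is multiplied by exp(sigma_ln * N).
    Each partner is independently unexpressed with probability `dropout`
    (IGF1R is always retained); partners absent in the base stay absent.
    """
    rng = np.random.default_rng(seed)
    panel = []
    for k in range(n_lines):
        copies = {}
        for p, c in base.copies.items():
            if c <= 0:
                copies[p] = 0.0
            elif p != RECEPTOR and rng.random() < dropout:
                copies[p] = 0.0
            else:
                copies[p] = float(c * np.exp(sigma_ln * rng.standard_normal()))
        panel.append(CellProfile(
            name=f"LINE{k + 1:02d}",
            copies=copies,
            tissue=tissues[k % len(tissues)],
        ))
    return panel


def hela_like_fixture() -> tuple:
    """A HeLa-S3-flavored (profile, map) transcribed from qualitative facts.

    Encoded facts: SHC1 binds only the juxtamembrane site Y980, which also
    recruits IRS1 and ZAP70; SHC1 is ~1e5 copies/cell, two orders above
    IRS1, and binds Y980 20-fold more tightly; STAT1 and CRKL are the two
    most abundant partners (~1e5-2e5); ABL2 is ninth in abundance (~1e4)
    but binds Y973 ~40-fold more tightly than CRKL; nine proteins compete
    for pY1161 including STAT1 and VAV2 at comparable high abundance and
    similar affinity; YES1 binds pY1161/pY1165 at ~0.9 uM; CRKL binds
    pY973 and pY1166; PIK3R2 binds pY1346; ITK and ZAP70 are not
    expressed.  All other values are synthetic choices within the observed
    ranges; this is NOT a measured dataset.
    """
    u = 1e-6  # molar per micromolar
    edges = [
        # Y980: juxtamembrane site
        ("SHC1", "Y980", 0.25 * u),
        ("IRS1", "Y980", 5.0 * u),        # 20x weaker than SHC1
        ("ZAP70", "Y980", 1.0 * u),
        # Y973
        ("ABL2", "Y973", 0.022 * u),      # ~40x stronger than CRKL
        ("CRKL", "Y973", 0.9 * u),
        ("CRK", "Y973", 2.5 * u),
        ("RASA1", "Y973", 1.5 * u),
        # Y1161: nine competitors
        ("STAT1", "Y1161", 0.4 * u),
        ("VAV2", "Y1161", 0.45 * u),
        ("YES1", "Y1161", 0.9 * u),
        ("SRC", "Y1161", 0.7 * u),
        ("PIK3R3", "Y1161", 1.0 * u),
        ("SYK", "Y1161", 1.5 * u),
        ("BLK", "Y1161", 2.0 * u),
        ("PLCG2", "Y1161", 2.5 * u),
        ("RASA1", "Y1161", 1.0 * u),
        # Y1165
        ("YES1", "Y1165", 0.9 * u),
        ("SRC", "Y1165", 1.0 * u),
        ("ITK", "Y1165", 1.5 * u),
        ("SYK", "Y1165", 1.2 * u),
        # Y1166
        ("CRKL", "Y1166", 0.7 * u),
        ("PIK3R1", "Y1166", 1.0 * u),
        ("RASA1", "Y1166", 0.5 * u),
        ("PLCG2", "Y1166", 2.0 * u),
        # Y1346
        ("PIK3R2", "Y1346", 0.4 * u),
        ("PIK3R1", "Y1346", 0.6 * u),
        ("PIK3R3", "Y1346", 1.2 * u),
        ("ZAP70", "Y1346", 2.5 * u),
    ]
    imap = InteractionMap.from_edges(tuple(edges))
    copies = {
        RECEPTOR: 2.0e4,
        "CRKL": 2.0e5, "STAT1": 1.7e5, "SHC1": 1.0e5, "VAV2": 8.0e4,
        "RASA1": 3.0e4, "CRK": 3.0e4, "YES1": 2.5e4, "SRC": 1.8e4,
        "ABL2": 1.2e4,
        "PIK3R1": 8.0e3, "PIK3R2": 6.0e3, "PLCG2": 2.0e3, "PIK3R3": 1.5e3,
        "SYK": 1.0e3, "IRS1": 1.0e3, "BLK": 4.0e2,
        "ITK": 0.0, "ZAP70": 0.0,
    }
    profile = CellProfile(name="HELA_S3_LIKE", copies=copies, tissue="CERV")
    return profile, imap


def full_scale_interaction_map(seed: int = 0) -> InteractionMap:
    """An 18-partner, 50-edge synthetic map (full-scale network size)."""
    return generate_interaction_map(
        SyntheticSpec(seed=seed, n_proteins=18, n_sites=6, n_edges=50)
    )


# ---------------------------------------------------------------------------
# Tab-separated table I/O (one header row, HGNC symbols, UTF-8)
# ---------------------------------------------------------------------------

def write_profile_tsv(profile: CellProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# name: {profile.name}\n")
        if profile.tissue:
            fh.write(f"# tissue: {profile.tissue}\n")
        fh.write(f"# provenance: {profile.provenance}\n")
        if profile.igf1r_anchor:
            fh.write(f"# igf1r_anchor: {profile.igf1r_anchor:.10g}\n")
        fh.write("protein\tcopies_per_cell\n")
        for p in sorted(profile.copies):
            fh.write(f"{p}\t{profile.copies[p]:.10g}\n")


def read_profile_tsv(path, name: str = None) -> CellProfile:
    meta = {"name": name or str(path), "tissue": "", "provenance": "absolute",
            "igf1r_anchor": None}
    copies = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                key = key.strip()
                if key in ("name", "tissue", "provenance"):
                    if not (key == "name" and name):
                        meta[key] = val.strip()
                elif key == "igf1r_anchor":
                    meta["igf1r_anchor"] = float(val)
                continue
            cols = line.split("\t")
            if cols[0] == "protein":
                continue
            if len(cols) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(cols)}")
            try:
                copies[cols[0]] = float(cols[1])
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: bad copy number {cols[1]!r}") from e
    return CellProfile(name=meta["name"], copies=copies, tissue=meta["tissue"],
                       provenance=meta["provenance"],
                       igf1r_anchor=meta["igf1r_anchor"])


def write_map_tsv(imap: InteractionMap, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# ka: {imap.ka:.10g}\n")
        fh.write("protein\tsite\tkd_uM\n")
        for p, s, kd in imap.edges:
            fh.write(f"{p}\t{s}\t{kd * 1e6:.10g}\n")


def read_map_tsv(path) -> InteractionMap:
    edges = []
    ka = 1.0e6
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                if key.strip() == "ka":
                    ka = float(val)
                continue
            cols = line.split("\t")
            if cols[0] == "protein":
                continue
            if len(cols) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(cols)}")
            try:
                edges.append((cols[0], cols[1], float(cols[2]) * 1e-6))
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: bad K_D {cols[2]!r}") from e
    return InteractionMap.from_edges(tuple(edges), ka=ka)


def read_supplementary_tables(profile_paths, map_path,
                              igf1r_anchor: float = None) -> tuple:
    """Load per-line copy tables + the K_D table; validate and reconcile.

    Relative-abundance profiles are rescaled to the IGF1R anchor (their own
    declared anchor, or the `igf1r_anchor` argument).  Protein symbols
    without any edge in the map (other than IGF1R) are excluded with a
    warning.  Returns (profiles, interaction_map, report).
    """
    imap = read_map_tsv(map_path)
    imap = imap.with_irs1_default() if _needs_irs1(imap) else imap
    known = set(imap.proteins) | {RECEPTOR}
    profiles, report = [], {"unknown_symbols": {}, "rescaled": [], "rejected": []}
    for path in profile_paths:
        prof = read_profile_tsv(path)
        unknown = sorted(set(prof.copies) - known)
        if unknown:
            warnings.warn(
                f"{prof.name}: excluding {len(unknown)} unknown symbol(s): "
                + ", ".join(unknown)
            )
            report["unknown_symbols"][prof.name] = unknown
            prof = CellProfile(
                name=prof.name,
                copies={p: c for p, c in prof.copies.items() if p in known},
                tissue=prof.tissue, provenance=prof.provenance,
                igf1r_anchor=prof.igf1r_anchor,
            )
        if prof.provenance == "relative":
            anchor = prof.igf1r_anchor or igf1r_anchor
            if not anchor:
                raise ValueError(f"{prof.name}: relative profile without an IGF1R anchor")
            prof = prof.rescaled_to_anchor(anchor)
            report["rescaled"].append(prof.name)
        if prof.igf1r_copies <= 0:
            report["rejected"].append(prof.name)
            continue
        profiles.append(prof)
    return profiles, imap, report


def _needs_irs1(imap: InteractionMap) -> bool:
    try:
        return not imap.edges_for("IRS1") and bool(dict(imap.edges_for("SHC1")).get("Y980"))
    except Exception:
        return False


def write_sidecar(path, **payload) -> None:
    """JSON sidecar recording the generation spec and seed."""
    def default(o):
        if isinstance(o, SyntheticSpec):
            return asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=default, sort_keys=True)
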