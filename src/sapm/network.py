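"""Directed signaling network: regions, edges, and latent (external) inputs.

The network is the topology over which all signaling is defined.  Regions are
named by canonical short codes (AC, PC, IC, ...); an alias table maps the long
anatomical names used in running text onto the short codes.  Edges are ordered
pairs (source, target) meaning "source's output signaling contributes to
target's input".  Latent inputs are unobserved external drives entering the
network at designated regions (e.g. Lat0 -> frontal orbital cortex).

Two fixtures ship with the package: ``brain`` (14 cortical/subcortical regions,
3 latent inputs) and ``brainstem_cord`` (10 brainstem and spinal-cord regions,
1 latent input to the locus coeruleus).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "NetworkModel",
    "NetworkValidationError",
    "NetworkParseError",
    "ValidationReport",
    "load_network",
    "save_network",
    "load_builtin_network",
    "validate_network",
    "canonical_region_name",
    "BUILTIN_NETWORKS",
]

#: long/variant anatomical names -> canonical short codes
REGION_ALIASES = {
    "anterior cingulate": "AC",
    "anterior cingulate cortex": "AC",
    "ACC": "AC",
    "posterior cingulate": "PC",
    "posterior cingulate cortex": "PC",
    "insular cortex": "IC",
    "insula": "IC",
    "heschl's gyrus": "HG",
    "heschls gyrus": "HG",
    "frontal orbital cortex": "FOrb",
    "F. Orb.": "FOrb",
    "F.Orb.": "FOrb",
    "FOrb.": "FOrb",
    "hippocampus": "Hippo",
    "Hippo.": "Hippo",
    "Hipp": "Hippo",
    "hypothalamus": "Hypo",
    "Hypo.": "Hypo",
    "Hypoth.": "Hypo",
    "amygdala": "Amyg",
    "Amyg.": "Amyg",
    "amgydala": "Amyg",
    "thalamus": "Thal",
    "Thal.": "Thal",
    "nucleus accumbens": "NAcc",
    "N. Accum.": "NAcc",
    "N.Accum.": "NAcc",
    "N. Acc.": "NAcc",
    "ventral tegmental area": "VTA",
    "periaqueductal gray": "PAG",
    "periaqueductal gray region": "PAG",
    "parabrachial nuclei": "PBN",
    "locus coeruleus": "LC",
    "nucleus tractus solitarius": "NTS",
    "nucleus gigantocellularis": "NGc",
    "nucleus raphe magnus": "NRM",
    "dorsal reticular nucleus": "DRt",
    "C6 right dorsal horn": "C6RD",
}


def canonical_region_name(name: str) -> str:
    """Map a long/variant anatomical name to its canonical short code.

    Unknown names are returned unchanged (users may define their own regions).
    """
    if name in REGION_ALIASES:
        return REGION_ALIASES[name]
    return REGION_ALIASES.get(name.lower(), name)


class NetworkParseError(ValueError):
    """Raised when a network spec file does not match the documented schema."""


class NetworkValidationError(ValueError):
    """Raised when a network violates a structural invariant.

    The message lists *all* failures, one per line.
    """


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of every invariant check on a network.

    ``checks`` is a list of (check name, passed, detail) triples; ``failures``
    collects the detail strings of failed checks.  An empty failure list means
    the network is usable by the fitting engine.
    """

    checks: list[tuple[str, bool, str]] = field(default_factory=list)

    @property
    def failures(self) -> list[str]:
        return [detail for _, ok, detail in self.checks if not ok]

    @property
    def ok(self) -> bool:
        return not self.failures


@dataclass(frozen=True)
class NetworkModel:
    """A directed signaling network.

    Parameters
    ----------
    regions : list of unique region short codes.
    edges : list of (source, target) region pairs; stored sorted by
        (source, target) so parameter vectors have a stable layout.
    latents : list of (latent name, target region) pairs.
    name : free-text label.
    """

    regions: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    latents: tuple[tuple[str, str], ...]
    name: str = ""

    def __init__(self, regions, edges=(), latents=(), name=""):
        object.__setattr__(self, "regions", tuple(canonical_region_name(r) for r in regions))
        canon_edges = tuple(
            sorted((canonical_region_name(s), canonical_region_name(t)) for s, t in edges)
        )
        object.__setattr__(self, "edges", canon_edges)
        object.__setattr__(
            self,
            "latents",
            tuple((str(ln), canonical_region_name(t)) for ln, t in latents),
        )
        object.__setattr__(self, "name", str(name))

    # -- structure queries -------------------------------------------------
    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_latents(self) -> int:
        return len(self.latents)

    @property
    def latent_names(self) -> tuple[str, ...]:
        return tuple(ln for ln, _ in self.latents)

    def region_index(self, region: str) -> int:
        return self.regions.index(canonical_region_name(region))

    def incoming(self, region: str) -> list[tuple[str, str]]:
        """All incoming connections of ``region``: network edges first, then
        latent edges, in canonical order."""
        region = canonical_region_name(region)
        inc = [(s, t) for s, t in self.edges if t == region]
        inc += [(ln, t) for ln, t in self.latents if t == region]
        return inc

    @property
    def connections(self) -> list[tuple[str, str]]:
        """All connections carrying D/B parameters: network edges then latent
        edges, in canonical (stable) order."""
        return list(self.edges) + list(self.latents)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`NetworkValidationError` listing all violations."""
        report = validate_network(self)
        if not report.ok:
            raise NetworkValidationError("\n".join(report.failures))

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "regions": list(self.regions),
            "edges": [list(e) for e in self.edges],
            "latents": [{"name": ln, "target": t} for ln, t in self.latents],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkModel":
        required = {"name", "regions", "edges", "latents"}
        missing = required - set(d)
        if missing:
            raise NetworkParseError(f"network spec missing fields: {sorted(missing)}")
        unknown = set(d) - required
        if unknown:
            raise NetworkParseError(f"network spec has unknown fields: {sorted(unknown)}")
        if not isinstance(d["regions"], list) or not all(isinstance(r, str) for r in d["regions"]):
            raise NetworkParseError("field 'regions' must be a list of strings")
        edges = []
        for e in d["edges"]:
            if not (isinstance(e, (list, tuple)) and len(e) == 2):
                raise NetworkParseError(f"field 'edges': entry {e!r} is not a 2-element list")
            edges.append((e[0], e[1]))
        latents = []
        for item in d["latents"]:
            if not (isinstance(item, dict) and {"name", "target"} <= set(item)):
                raise NetworkParseError(
                    f"field 'latents': entry {item!r} must be a dict with 'name' and 'target'"
                )
            latents.append((item["name"], item["target"]))
        return cls(regions=d["regions"], edges=edges, latents=latents, name=d["name"])


def validate_network(net: NetworkModel) -> ValidationReport:
    """Check every structural invariant; never raises (reporting operation)."""
    checks: list[tuple[str, bool, str]] = []

    dupes = sorted({r for r in net.regions if list(net.regions).count(r) > 1})
    checks.append(
        ("unique_region_names", not dupes, f"duplicate region names: {dupes}" if dupes else "")
    )

    regions = set(net.regions)
    bad_endpoints = sorted(
        {r for e in net.edges for r in e if r not in regions}
        | {t for _, t in net.latents if t not in regions}
    )
    checks.append(
        (
            "edge_endpoints_declared",
            not bad_endpoints,
            f"edge/latent endpoints not declared as regions: {bad_endpoints}" if bad_endpoints else "",
        )
    )

    seen, dup_edges = set(), []
    for e in net.edges:
        if e in seen:
            dup_edges.append(e)
        seen.add(e)
    checks.append(
        (
            "no_duplicate_edges",
            not dup_edges,
            f"duplicate edges: {[f'{s}->{t}' for s, t in dup_edges]}" if dup_edges else "",
        )
    )

    loops = [e for e in net.edges if e[0] == e[1]]
    checks.append(
        (
            "no_self_loops",
            not loops,
            f"self-loop edges: {[f'{s}->{t}' for s, t in loops]}" if loops else "",
        )
    )

    fed = {t for _, t in net.edges} | {t for _, t in net.latents}
    inputless = sorted(r for r in regions if r not in fed)
    checks.append(
        (
            "every_region_has_input",
            not inputless,
            f"regions with no incoming edge or latent input: {inputless}" if inputless else "",
        )
    )
    return ValidationReport(checks=checks)


def load_network(path: str | Path) -> NetworkModel:
    """Load and validate a network spec file (JSON or YAML).

    Schema: keys ``name``, ``regions`` (list), ``edges`` (list of 2-element
    lists), ``latents`` (list of ``{name, target}``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    try:
        if path.suffix in (".yaml", ".yml"):
            d = yaml.safe_load(text)
        else:
            d = json.loads(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise NetworkParseError(f"cannot parse network spec {path}: {exc}") from exc
    if not isinstance(d, dict):
        raise NetworkParseError(f"network spec {path} must be a mapping")
    net = NetworkModel.from_dict(d)
    net.validate()
    return net


def save_network(net: NetworkModel, path: str | Path) -> Path:
    """Write a network spec (JSON or YAML by extension); round-trips with
    :func:`load_network`."""
    path = Path(path)
    d = net.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2))
    return path


BUILTIN_NETWORKS = ("brain", "brainstem_cord", "demo_small")


def load_builtin_network(name: str) -> NetworkModel:
    """Load a bundled network fixture: ``brain``, ``brainstem_cord``, or the
    small ``demo_small`` network used by the demo pipeline and calibration."""
    if name not in BUILTIN_NETWORKS:
        raise KeyError(f"unknown builtin network {name!r}; choose from {BUILTIN_NETWORKS}")
    ref = resources.files("sapm.data").joinpath(f"{name}.json")
    net = NetworkModel.from_dict(json.loads(ref.read_text()))
    net.validate()
    return net
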