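"""Metagenomic functional modules: KEGG-syntax definitions and abundances.

A metabolic module is a short enzymatic pathway written in KEGG database
syntax: space-separated reaction *steps*, comma-separated *alternative*
orthologs within a step, ``+``-joined subunits of a *complex* (all
required), ``-``-prefixed optional components, and parenthesised groups.
Per-sample module abundance follows the Omixer-RPM conventions:
alternatives take the max, complexes the min, and the module value is the
median over step abundances, reported only when enough steps are covered.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from itertools import product

import numpy as np
import pandas as pd

from .stats import adjust_pvalues
from scipy.stats import spearmanr

__all__ = [
    "Alternative",
    "ModuleDefinition",
    "ModuleProfile",
    "RichnessResult",
    "ModuleParseError",
    "parse_module_definition",
    "read_module_blocks",
    "load_synthetic_modules",
    "module_abundance",
    "module_profiles",
    "gene_richness",
    "shannon_diversity",
    "associate_modules",
]

logger = logging.getLogger(__name__)

_TOKEN_RE = re.compile(r"[A-Za-z0-9_.]+")


class ModuleParseError(ValueError):
    """Raised for malformed KEGG-syntax module definitions."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class Alternative:
    """One way of realising a step: all ``required`` orthologs present."""

    required: frozenset
    optional: frozenset = frozenset()

    def sort_key(self):
        return (sorted(self.required), sorted(self.optional))


@dataclass
class ModuleDefinition:
    """A parsed metabolic module.

    ``steps`` is a list (AND over steps) of OR-lists of :class:`Alternative`
    in disjunctive normal form, so evaluation is max-over-alternatives of
    min-over-required-orthologs at every step.
    """

    module_id: str
    name: str
    definition: str
    steps: list = field(default_factory=list)

    @property
    def orthologs(self) -> frozenset:
        out = set()
        for step in self.steps:
            for alt in step:
                out |= alt.required | alt.optional
        return frozenset(out)

    def to_definition_string(self) -> str:
        """Canonical serialisation (sorted DNF); reparsing is a fixed point."""
        parts = []
        for step in self.steps:
            alts = []
            for alt in sorted(step, key=Alternative.sort_key):
                body = "+".join(sorted(alt.required))
                for opt in sorted(alt.optional):
                    body += f"-{opt}"
                alts.append(f"({body})" if ("+" in body or "-" in body) else body)
            parts.append(",".join(alts))
        return " ".join(parts)


def _split_top(text: str, seps: str, offset: int) -> list[tuple[str, int]]:
    """Split on separator chars at paren depth 0, keeping offsets."""
    parts, depth, start = [], 0, 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ModuleParseError("unbalanced ')'", offset + i)
        elif ch in seps and depth == 0:
            parts.append((text[start:i], offset + start))
            start = i + 1
    if depth != 0:
        raise ModuleParseError("unbalanced '('", offset + len(text))
    parts.append((text[start:], offset + start))
    return parts


def _and_combine(alt_lists: list[list[Alternative]]) -> list[Alternative]:
    combined = [Alternative(frozenset(), frozenset())]
    for alts in alt_lists:
        combined = [
            Alternative(a.required | b.required, a.optional | b.optional)
            for a, b in product(combined, alts)
        ]
    # deduplicate
    return sorted(set(combined), key=Alternative.sort_key)


def _parse_expr(text: str, offset: int) -> list[Alternative]:
    """Space-separated sequence inside a group: AND of its parts."""
    parts = [p for p in _split_top(text, " ", offset) if p[0].strip() or True]
    return _and_combine([_parse_step(p, o) for p, o in parts])


def _parse_step(text: str, offset: int) -> list[Alternative]:
    """Comma list: OR over alternatives."""
    alts: list[Alternative] = []
    for part, off in _split_top(text, ",", offset):
        if not part.strip():
            raise ModuleParseError("empty alternative", off)
        alts.extend(_parse_complex(part, off))
    return sorted(set(alts), key=Alternative.sort_key)


def _parse_complex(text: str, offset: int) -> list[Alternative]:
    """``+``/``-`` joined components: AND, with ``-`` marking optional."""
    # split on top-level + and -, remembering the sign preceding each chunk
    chunks, depth, start, signs = [], 0, 0, ["+"]
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        elif ch in "+-" and depth == 0 and i > start:
            chunks.append((text[start:i], offset + start))
            signs.append(ch)
            start = i + 1
    chunks.append((text[start:], offset + start))

    required_lists, optional = [], set()
    for (chunk, off), sign in zip(chunks, signs):
        chunk = chunk.strip()
        if not chunk:
            raise ModuleParseError("empty component", off)
        if chunk.startswith("(") and chunk.endswith(")"):
            inner = _parse_expr(chunk[1:-1], off + 1)
            if not chunk[1:-1].strip():
                raise ModuleParseError("empty group", off)
            if sign == "+":
                required_lists.append(inner)
            else:  # optional group: all its orthologs become optional
                for alt in inner:
                    optional |= alt.required | alt.optional
        else:
            if not _TOKEN_RE.fullmatch(chunk):
                raise ModuleParseError(f"invalid token {chunk!r}", off)
            if sign == "+":
                required_lists.append([Alternative(frozenset({chunk}))])
            else:
                optional.add(chunk)
    if not required_lists:
        # a purely optional complex contributes nothing mandatory
        return [Alternative(frozenset(), frozenset(optional))]
    alts = _and_combine(required_lists)
    if optional:
        alts = [Alternative(a.required, a.optional | frozenset(optional)) for a in alts]
    return alts


def parse_module_definition(
    text: str, module_id: str = "", name: str = ""
) -> ModuleDefinition:
    """Parse one KEGG-syntax definition string into a step tree.

    >>> parse_module_definition("K00001 K00002,K00003").steps
    [[Alternative(required=frozenset({'K00001'}), ...)], [...2 alternatives...]]
    """
    stripped = " ".join(text.split())
    if not stripped:
        raise ModuleParseError("empty definition", 0)
    steps = []
    for part, off in _split_top(stripped, " ", 0):
        if not part.strip():
            raise ModuleParseError("empty step", off)
        steps.append(_parse_step(part, off))
    return ModuleDefinition(module_id=module_id, name=name, definition=stripped, steps=steps)


def read_module_blocks(text: str) -> list[ModuleDefinition]:
    """Read modules from the plain-text block format.

    Each block is an ``ID<tab>NAME`` line followed by one definition line;
    blocks are separated by blank lines. Lines starting with ``#`` are
    comments.
    """
    defs = []
    lines = [ln for ln in text.splitlines() if not ln.startswith("#")]
    blocks, current = [], []
    for ln in lines:
        if ln.strip():
            current.append(ln)
        elif current:
            blocks.append(current)
            current = []
    if current:
        blocks.append(current)
    for block in blocks:
        if len(block) != 2:
            raise ValueError(
                f"malformed module block (expected header + definition): {block!r}"
            )
        header, definition = block
        module_id, _, name = header.partition("\t")
        defs.append(parse_module_definition(definition, module_id.strip(), name.strip()))
    return defs


def load_synthetic_modules() -> list[ModuleDefinition]:
    """The 20 bundled synthetic phenylpropanoid-pathway module definitions.

    These are syntactically valid KEGG-style stand-ins (synthetic ortholog
    content) for a curated gut phenylpropanoid module set; real curated
    definitions in the same block format are drop-in replacements.
    """
    text = (
        resources.files("gutmet.data")
        .joinpath("gut_modules_synthetic.txt")
        .read_text()
    )
    return read_module_blocks(text)


@dataclass
class ModuleProfile:
    """Per-sample abundance and coverage of one module."""

    module_id: str
    name: str
    abundance: pd.Series  # 0 where not detected
    coverage: pd.Series  # fraction of steps with positive abundance
    detected: pd.Series  # coverage >= cutoff
    coverage_cutoff: float

    @property
    def prevalence(self) -> float:
        """Fraction of subjects in which the module is detected."""
        return float(self.detected.mean())


def module_abundance(
    defn: ModuleDefinition, kos: pd.DataFrame, coverage_cutoff: float = 2 / 3
) -> ModuleProfile:
    """Omixer-RPM-style per-sample module abundance.

    Step abundance is the max over alternatives of the min over a
    complex's required orthologs (a bare ortholog is its own abundance,
    absent orthologs count 0); coverage is the fraction of steps with
    positive abundance; the module abundance is the median over step
    abundances when coverage reaches ``coverage_cutoff``, else 0.
    """
    if not 0.0 <= coverage_cutoff <= 1.0:
        raise ValueError("coverage_cutoff must be in [0, 1]")
    X = kos.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("KO abundances must be nonnegative")
    col = {k: i for i, k in enumerate(kos.columns)}
    missing = sorted(defn.orthologs - set(col))
    if missing:
        logger.info(
            "module %s: %d ortholog(s) absent from KO table (treated as 0): %s",
            defn.module_id, len(missing), ", ".join(missing),
        )
    n = X.shape[0]
    step_values = np.zeros((n, len(defn.steps)))
    for s, alternatives in enumerate(defn.steps):
        best = np.zeros(n)
        for alt in alternatives:
            if not alt.required:
                continue
            idx = [col.get(k) for k in alt.required]
            if any(i is None for i in idx):
                continue  # an absent required ortholog makes the min 0
            np.maximum(best, X[:, idx].min(axis=1), out=best)
        step_values[:, s] = best
    coverage = (step_values > 0).mean(axis=1)
    detected = coverage >= coverage_cutoff
    abundance = np.where(detected, np.median(step_values, axis=1), 0.0)
    idx = kos.index
    return ModuleProfile(
        module_id=defn.module_id,
        name=defn.name,
        abundance=pd.Series(abundance, index=idx, name=defn.module_id),
        coverage=pd.Series(coverage, index=idx, name="coverage"),
        detected=pd.Series(detected, index=idx, name="detected"),
        coverage_cutoff=coverage_cutoff,
    )


def module_profiles(
    definitions: list[ModuleDefinition], kos: pd.DataFrame, coverage_cutoff: float = 2 / 3
) -> list[ModuleProfile]:
    return [module_abundance(d, kos, coverage_cutoff) for d in definitions]


@dataclass
class RichnessResult:
    """Per-subject detected-gene counts and the high/low richness split."""

    gene_count: pd.Series
    richness_class: pd.Series  # "high" iff gene_count > cutoff
    shannon_index: pd.Series | None
    cutoff: float


def gene_richness(
    table: pd.DataFrame,
    detection_threshold: float = 0.0,
    cutoff: float = 480_000,
    genus_table: pd.DataFrame | None = None,
) -> RichnessResult:
    """Count detected genes/orthologs per subject and classify richness.

    The default cutoff of 480 000 genes is the published high/low gene-count
    boundary for human shotgun catalogues; for ortholog-level or synthetic
    tables pass a cutoff on the scale of the table.
    """
    X = table.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("abundances must be nonnegative")
    counts = (X > detection_threshold).sum(axis=1)
    gene_count = pd.Series(counts, index=table.index, name="gene_count")
    richness_class = pd.Series(
        np.where(counts > cutoff, "high", "low"), index=table.index, name="richness_class"
    )
    shannon = shannon_diversity(genus_table) if genus_table is not None else None
    return RichnessResult(gene_count, richness_class, shannon, cutoff)


def shannon_diversity(genus_table: pd.DataFrame) -> pd.Series:
    """Shannon index H = −Σ pᵢ ln pᵢ (nats) per subject."""
    X = genus_table.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("counts must be nonnegative")
    totals = X.sum(axis=1)
    zero = totals <= 0
    if zero.any():
        names = [str(genus_table.index[i]) for i in np.flatnonzero(zero)]
        raise ValueError("all-zero composition for subjects: " + ", ".join(names))
    p = X / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(p > 0, p * np.log(p), 0.0).sum(axis=1)
    return pd.Series(h, index=genus_table.index, name="shannon")


def associate_modules(
    profiles: list[ModuleProfile],
    response: pd.Series | np.ndarray,
    prevalence_min: float = 0.2,
    fdr_method: str = "storey_q",
) -> pd.DataFrame:
    """Spearman association of prevalent modules with a response.

    Modules with prevalence strictly above ``prevalence_min`` (the
    ">20 %" convention) are correlated with the response; q-values come
    from ``fdr_method`` (Storey by default). Returns a table sorted by q.
    """
    y = np.asarray(response, dtype=float)
    rows = []
    for prof in profiles:
        if len(prof.abundance) != len(y):
            raise ValueError(f"module {prof.module_id}: length mismatch with response")
        if prof.prevalence > prevalence_min:
            rho, p = spearmanr(prof.abundance.to_numpy(), y)
            rows.append(
                {
                    "module_id": prof.module_id,
                    "name": prof.name,
                    "prevalence": prof.prevalence,
                    "rho": float(rho),
                    "p": max(float(p), np.finfo(float).tiny),
                }
            )
    if not rows:
        out = pd.DataFrame(
            columns=["module_id", "name", "prevalence", "rho", "p", "q"]
        )
        out.attrs["note"] = "no module passed the prevalence filter"
        return out
    table = pd.DataFrame(rows)
    table["q"] = adjust_pvalues(table["p"].to_numpy(), method=fdr_method)
    return table.sort_values("q", kind="stable").reset_index(drop=True)
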