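"""Plain-text configuration (INI ``key = value`` sections).

Two sections are understood:

``[decision]`` mirrors :class:`~secmdecon.decision.DecisionConfig`::

    [decision]
    pre_loss = 1.8
    pre_gain = 2.2
    post_loss = 1.5
    post_gain = 2.5
    min_cpg = 2
    max_fraction = 0.0
    mode = integrated
    min_post_reads = 10000

``[signature.<name>]`` overrides or defines a cell-type signature::

    [signature.custom]
    f_zero = 0.40
    f_partial = 0.12
    f_full = 0.48
"""

from __future__ import annotations

import configparser
from pathlib import Path

from .cnv import ThresholdPair
from .decision import DecisionConfig
from .decontam import FilterPolicy
from .errors import FormatError
from .simulate import CellTypeSignature, builtin_signatures

_SIG_FLOATS = ("f_zero", "f_partial", "f_full", "partial_alpha", "partial_beta",
               "tail_p", "genome_level")


def _read(path) -> configparser.ConfigParser:
    cp = configparser.ConfigParser()
    text = Path(path).read_text()
    try:
        cp.read_string(text)
    except configparser.Error as exc:
        raise FormatError(f"{path}: cannot parse config: {exc}") from exc
    return cp


def load_decision_config(path) -> DecisionConfig:
    cp = _read(path)
    if "decision" not in cp:
        return DecisionConfig()
    s = cp["decision"]
    return DecisionConfig(
        pre_thresholds=ThresholdPair(s.getfloat("pre_loss", 1.8), s.getfloat("pre_gain", 2.2)),
        post_thresholds=ThresholdPair(s.getfloat("post_loss", 1.5), s.getfloat("post_gain", 2.5)),
        filter_policy=FilterPolicy(min_cpg=s.getint("min_cpg", 2),
                                   max_fraction=s.getfloat("max_fraction", 0.0)),
        mode=s.get("mode", "integrated"),
        min_post_reads=s.getint("min_post_reads", 10_000),
    )


def load_signatures(path) -> dict[str, CellTypeSignature]:
    """Built-in registry updated/extended by ``[signature.<name>]`` sections."""
    cp = _read(path)
    registry = builtin_signatures()
    for section in cp.sections():
        if not section.startswith("signature."):
            continue
        name = section.split(".", 1)[1]
        base = registry.get(name)
        kw = {k: base and getattr(base, k) for k in _SIG_FLOATS} if base else {}
        kw = {k: v for k, v in kw.items() if v is not None}
        for key in _SIG_FLOATS:
            if key in cp[section]:
                kw[key] = cp[section].getfloat(key)
        if "cpg_histogram" in cp[section]:
            kw["cpg_histogram"] = tuple(
                float(x) for x in cp[section]["cpg_histogram"].split(","))
        elif base is not None:
            kw["cpg_histogram"] = base.cpg_histogram
        for req in ("f_zero", "f_partial", "f_full"):
            if req not in kw:
                raise FormatError(f"[{section}]: missing {req}")
        registry[name] = CellTypeSignature(name=name, **kw)
    return registry
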