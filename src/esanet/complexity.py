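"""Parameter and multiply–accumulate (MAC) audit with per-layer breakdown.

Counting convention (calibrated once against the published reference audit
of the nine comparison models at a 61-class head and input (1, 3, 224, 224),
then frozen — every baseline row reproduces to two decimals):

* convolution: ``output_elements × (k_h·k_w·C_in / groups [+ 1 if bias])``
* linear: ``batch × in_features × out_features``
* affine batch normalization: ``4 × elements`` (2 × elements if not affine)
* activations, pooling, dropout, attention pooling/sigmoid: 0

The audited quantity is multiply–accumulates; the human-readable report
prints it under a "GFlops" alias because that is the label the reference
audit uses for the same numbers.

Counting is purely analytic (static shape propagation over the layer graph);
no forward pass is executed, so the full audit of all models takes seconds.
"""

from __future__ import annotations

import decimal
import json
from dataclasses import dataclass, field

from . import nn
from .backbone import (ArchitectureSpec, Classifier, build_esa_resnet34,
                       build_reference_model)

#: Published complexity audit this module is calibrated against:
#: model name -> (params in 1e6, MACs in 1e9), both rounded to 2 decimals.
PUBLISHED_AUDIT: dict[str, tuple[float, float]] = {
    "vgg16": (134.51, 15.48),
    "alexnet": (57.25, 0.71),
    "densenet121": (7.02, 2.90),
    "resnet18": (11.21, 1.82),
    "resnet34": (21.32, 3.68),
    "resnet50": (23.63, 4.13),
    "resnet101": (42.63, 7.86),
    "resnet152": (58.27, 11.60),
    "ours": (3.12, 0.57),
}

#: Head width under which the published audit's "ours" row was produced.
#: The published parameter total (3.12 M) is only consistent with the
#: framework-default 1000-way classifier head — the gap to a 61-class head
#: is exactly (512+1)×939 scalars, the head-resize arithmetic — whereas all
#: baseline rows are consistent with 61-way heads. The parity audit
#: therefore profiles the proposed architecture with a 1000-way head; MACs
#: are insensitive to the choice (0.57 G either way).
AUDIT_HEAD_CLASSES = 1000

AUDIT_INPUT_SHAPE = (1, 3, 224, 224)


def round_half_up(x: float, decimals: int = 2) -> float:
    q = decimal.Decimal(1).scaleb(-decimals)
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass
class ComplexityReport:
    """Per-layer and total parameter/MAC audit at a stated input shape."""

    model_name: str
    input_shape: tuple[int, int, int, int]
    rows: list[tuple[str, str, int, int]] = field(default_factory=list)

    @property
    def total_params(self) -> int:
        return sum(r[2] for r in self.rows)

    @property
    def total_macs(self) -> int:
        return sum(r[3] for r in self.rows)

    @property
    def params_m(self) -> float:
        """Parameters in millions, rounded half-up to 2 decimals."""
        return round_half_up(self.total_params / 1e6)

    @property
    def macs_g(self) -> float:
        """MACs in units of 1e9 ("GFlops" in the published audit's label)."""
        return round_half_up(self.total_macs / 1e9)

    def to_json(self) -> str:
        return json.dumps({
            "model": self.model_name,
            "input_shape": list(self.input_shape),
            "convention": ("conv=out*k*k*Cin/groups(+bias); linear=in*out; "
                           "affine_bn=4*elems; act/pool=0"),
            "total_params": self.total_params,
            "total_macs": self.total_macs,
            "params_M": self.params_m,
            "gflops": self.macs_g,
            "rows": [{"layer": n, "kind": k, "params": p, "macs": m}
                     for n, k, p, m in self.rows],
        }, indent=2)

    def to_tsv(self) -> str:
        lines = ["layer\tkind\tparams\tmacs"]
        lines += [f"{n}\t{k}\t{p}\t{m}" for n, k, p, m in self.rows]
        lines.append(f"TOTAL\t{self.model_name}\t{self.total_params}\t{self.total_macs}")
        return "\n".join(lines)


def count_parameters(model: nn.Module) -> int:
    """Exact number of learnable scalars, by enumerating the model's state."""
    return sum(p.size for p in model.parameters())


def count_macs(model: nn.Module, input_shape=AUDIT_INPUT_SHAPE) -> int:
    """Total multiply–accumulates at ``input_shape``, frozen convention above.

    The layer graph is static (there is no data-dependent control flow in
    this package's models), so the count is exact and deterministic.
    """
    rows, _ = model.profile_rows(tuple(input_shape))
    return sum(r[3] for r in rows)


def profile_model(model: nn.Module, input_shape=AUDIT_INPUT_SHAPE,
                  name: str | None = None) -> ComplexityReport:
    """Full per-layer audit of ``model`` at ``input_shape``."""
    rows, _ = model.profile_rows(tuple(input_shape))
    return ComplexityReport(
        model_name=name or getattr(model, "name", type(model).__name__),
        input_shape=tuple(input_shape), rows=list(rows))


def build_audit_model(name: str, num_classes: int | None = None) -> Classifier:
    """Build the model the published audit profiled under ``name``.

    Baselines use a 61-class head; ``"ours"`` uses the calibrated parity
    configuration (see :data:`AUDIT_HEAD_CLASSES`). Pass ``num_classes`` to
    override.
    """
    if name == "ours":
        spec = ArchitectureSpec(num_classes=num_classes or AUDIT_HEAD_CLASSES)
        return build_esa_resnet34(spec)
    return build_reference_model(name, num_classes or 61)


def reduction_percent(baseline: float, reduced: float) -> float:
    """``100 × (1 − reduced/baseline)``, rounded half-up to two decimals."""
    if baseline <= 0:
        raise ValueError(f"baseline must be positive, got {baseline}")
    return round_half_up(100.0 * (1.0 - reduced / baseline))


def paper_table(names=None, input_shape=AUDIT_INPUT_SHAPE):
    """Recompute the published audit side by side with the reference values.

    Returns a list of dicts with recomputed and published params/MACs and a
    ``"pass"`` flag (two-decimal agreement on both columns).
    """
    out = []
    for name in (names or PUBLISHED_AUDIT):
        ref_p, ref_g = PUBLISHED_AUDIT[name]
        rep = profile_model(build_audit_model(name), input_shape, name=name)
        out.append({
            "model": name,
            "params_M": rep.params_m, "ref_params_M": ref_p,
            "gflops": rep.macs_g, "ref_gflops": ref_g,
            "pass": rep.params_m == ref_p and rep.macs_g == ref_g,
        })
    return out
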