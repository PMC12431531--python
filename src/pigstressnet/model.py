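"""Assembly and accounting of the nano-scale detector variants.

``build_model`` constructs the YOLOv12n-style baseline (backbone with
C3k2/A2C2f blocks and area attention, FPN/PAN neck, dual-branch head)
and inserts, under independent flags,

* NAM channel attention after the last backbone A2C2f block,
* the RCM after the second neck A2C2f block (the P3 branch), and
* the MBConv localization head (MBHead),

which yields the four ablation variants plus the full model.

``count_params`` reports the deployed (BN-fused) parameter count, the
convention of framework model summaries: framework Conv blocks fold
their batch norm into the convolution (one bias per channel survives),
while the custom NAM/RCM/MBConv blocks keep their norm affine pairs,
exactly as a framework fuse pass would leave them.  ``count_flops``
counts convolution multiply–accumulates times two at a given input
size; elementwise work and attention tensor products are excluded.  The
convention was calibrated once on the baseline and is applied unchanged
to every variant, so deltas and ratios are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .attention import NAMChannel, NAMSpatial, RCM
from .blocks import A2C2f, C3k2
from .heads import DetectHead, HeadSpec
from .nn.modules import Concat, Conv, Module, ModuleList, Sequential, Upsample

CLASS_NAMES = ("stand", "eat", "sit", "lying", "stress")


@dataclass
class ModelSpec:
    """Declarative description of one detector variant."""
    n_classes: int = 5
    use_nam: bool = False
    use_rcm: bool = False
    use_mbhead: bool = False
    loss: str = "ciou"
    input_size: int = 640
    nam_spatial: bool = False      # spatial submodule; off by default
    rcm_strip_kernel: int = 11
    rcm_mlp_expansion: int = 2

    def __post_init__(self):
        if self.loss not in ("ciou", "mpdiou"):
            raise ValueError("loss must be 'ciou' or 'mpdiou'")


VARIANTS = {
    "baseline": {},
    "nam": {"use_nam": True},
    "rcm": {"use_rcm": True},
    "mbhead": {"use_mbhead": True},
    "mpdiou": {"loss": "mpdiou"},
    "full": {"use_nam": True, "use_rcm": True, "use_mbhead": True,
             "loss": "mpdiou"},
}


def spec_for(variant: str, **overrides) -> ModelSpec:
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {sorted(VARIANTS)}")
    kw = dict(VARIANTS[variant])
    kw.update(overrides)
    return ModelSpec(**kw)


class PigStressNet(Module):
    """The detector: 21 wired stages plus the detection head."""

    def __init__(self, spec: ModelSpec):
        super().__init__()
        self.spec = spec
        s = spec

        def stage(*mods):
            return mods[0] if len(mods) == 1 else Sequential(*mods)

        backbone_tail = [A2C2f(256, 256, 2, a2=True, area=1)]
        if s.use_nam:
            backbone_tail.append(NAMChannel(256))
            if s.nam_spatial:
                p5 = s.input_size // 32
                backbone_tail.append(NAMSpatial(p5, p5))

        p3_tail = [A2C2f(256, 64, 1, a2=False)]
        if s.use_rcm:
            p3_tail.append(RCM(64, s.rcm_strip_kernel, s.rcm_mlp_expansion))

        # (module, input indices) — index -1 is the previous stage
        self.wiring = [
            (Conv(3, 16, 3, 2), [-1]),                 # 0  P1/2
            (Conv(16, 32, 3, 2), [-1]),                # 1  P2/4
            (C3k2(32, 64, 1, c3k=False, e=0.25), [-1]),    # 2
            (Conv(64, 64, 3, 2), [-1]),                # 3  P3/8
            (C3k2(64, 128, 1, c3k=False, e=0.25), [-1]),   # 4
            (Conv(128, 128, 3, 2), [-1]),              # 5  P4/16
            (A2C2f(128, 128, 2, a2=True, area=4), [-1]),   # 6
            (Conv(128, 256, 3, 2), [-1]),              # 7  P5/32
            (stage(*backbone_tail), [-1]),             # 8  (+ NAM)
            (Upsample(2), [-1]),                       # 9
            (Concat(), [-1, 6]),                       # 10
            (A2C2f(384, 128, 1, a2=False), [-1]),      # 11
            (Upsample(2), [-1]),                       # 12
            (Concat(), [-1, 4]),                       # 13
            (stage(*p3_tail), [-1]),                   # 14 (+ RCM)  P3 out
            (Conv(64, 64, 3, 2), [-1]),                # 15
            (Concat(), [-1, 11]),                      # 16
            (A2C2f(192, 128, 1, a2=False), [-1]),      # 17 P4 out
            (Conv(128, 128, 3, 2), [-1]),              # 18
            (Concat(), [-1, 8]),                       # 19
            (C3k2(384, 256, 1, c3k=True, e=0.5), [-1]),    # 20 P5 out
        ]
        self.stages = ModuleList(m for m, _ in self.wiring)
        self.froms = [f for _, f in self.wiring]
        self.head_levels = (14, 17, 20)
        self.head = DetectHead(HeadSpec(
            n_classes=s.n_classes,
            variant="mbhead" if s.use_mbhead else "baseline"))

    def forward(self, x):
        outs = []
        for stage, frm in zip(self.stages, self.froms):
            ins = [outs[i] if i != -1 else (outs[-1] if outs else x) for i in frm]
            outs.append(stage(ins if isinstance(stage, Concat) else ins[0]))
        return self.head([outs[i] for i in self.head_levels])

    @property
    def nam_gammas(self):
        """Scale vectors of every NAM submodule (for the L1 penalty):
        channel gammas and, when enabled, spatial lambdas."""
        out = []
        for m in self.modules():
            if isinstance(m, NAMChannel):
                out.append(m.bn.gamma)
            elif isinstance(m, NAMSpatial):
                out.append(m.lam)
        return out


def build_model(spec: ModelSpec, init_seed: int | None = None) -> PigStressNet:
    if init_seed is not None:
        from .nn.modules import set_init_seed
        set_init_seed(init_seed)
    return PigStressNet(spec)


@dataclass
class Profile:
    total_params: int
    total_flops: float                      # GFLOPs at the profiled input size
    per_module: list = field(default_factory=list)   # (name, params, gflops)

    def as_dict(self):
        return {
            "total_params": self.total_params,
            "total_gflops": round(self.total_flops, 4),
            "per_module": [(n, p, round(f, 4)) for n, p, f in self.per_module],
        }


def count_params(model: PigStressNet) -> int:
    """Deployed (BN-fused) trainable-scalar count, enumerated structurally."""
    return sum(m.deployed_param_count() for m in model.stages) + \
        model.head.deployed_param_count()


def _stage_profile(stage, c_in, h, w):
    """(macs, h_out, w_out) for one top-level stage at input h x w."""
    if isinstance(stage, Conv):
        ho, wo = h // stage.s, w // stage.s
        return stage.macs(ho, wo), ho, wo
    if isinstance(stage, Upsample):
        return 0, h * stage.scale, w * stage.scale
    if isinstance(stage, Concat):
        return 0, h, w
    if isinstance(stage, Sequential):
        macs = 0
        for child in stage:
            m, h, w = _stage_profile(child, c_in, h, w)
            macs += m
        return macs, h, w
    # shape-preserving composite blocks
    return stage.profile(h, w), h, w


def count_flops(model: PigStressNet, input_size: int | None = None,
                detailed: bool = False):
    """GFLOPs (2 x conv MACs) of one forward pass at a square input."""
    size = input_size or model.spec.input_size
    shapes = []          # (h, w) output of each stage
    per_module = []
    total = 0
    h = w = size
    for i, (stage, frm) in enumerate(zip(model.stages, model.froms)):
        src = frm[0]
        if i == 0:
            hin, win = size, size
        else:
            hin, win = shapes[src if src != -1 else i - 1]
        macs, ho, wo = _stage_profile(stage, None, hin, win)
        shapes.append((ho, wo))
        total += macs
        per_module.append((f"stage{i}:{type(stage).__name__}", macs))
    sizes = [shapes[i] for i in model.head_levels]
    head_levels = model.head.profile_levels(sizes)
    head_macs = sum(l + c for l, c in head_levels)
    total += head_macs
    per_module.append(("head:DetectHead", head_macs))
    gflops = 2.0 * total / 1e9
    if detailed:
        return gflops, per_module
    return gflops


def profile_model(spec: ModelSpec, input_size: int | None = None) -> Profile:
    """Build a variant and return its exact parameter/FLOPs breakdown."""
    model = build_model(spec)
    gflops, per_macs = count_flops(model, input_size, detailed=True)
    names_params = [(n, m.deployed_param_count())
                    for n, m in zip((p[0] for p in per_macs), model.stages)]
    names_params.append(("head:DetectHead", model.head.deployed_param_count()))
    per_module = [(n, p, 2.0 * macs / 1e9)
                  for (n, p), (_, macs) in zip(names_params, per_macs)]
    return Profile(count_params(model), gflops, per_module)
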