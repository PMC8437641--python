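"""Small ablation study of the four segmentation variants on phantoms.

LR   : decomposition on the raw angiography ROI (no fundus image)
LRM  : vessel inpainting + decomposition (the baseline)
LRM_to_R  : region growing seeded by the baseline, growth output only
LRM_plus_R: baseline mask fused with the grown regions (joint framework)
"""

from cscrseg import (PhantomSpec, RunConfig, ablation_study, phantom_batch,
                     summarize_ablation)

phantoms = phantom_batch(4, PhantomSpec(rng_seed=42))
table = ablation_study(phantoms, T_grid=(0.14, 0.18), config=RunConfig())
summary = summarize_ablation(table)

print(summary[["variant", "T", "f1_score", "sensitivity", "accuracy",
               "specificity"]].round(3).to_string(index=False))
print("\n(the decomposition-only variants carry no threshold dependence; "
      "the joint framework should lead in F1 and sensitivity, and skipping "
      "the multimodal inpainting (LR) lets bright vessels flood the "
      "sparse part)")
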