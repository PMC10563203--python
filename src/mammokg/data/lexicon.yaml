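# Canonical BI-RADS surface forms per feature type, with the variant and
# semantic-replacement tables used for knowledge fusion.  Canonical terms
# follow the preferred wording of the mammography reporting lexicon.
#
# Every listed variant is closer (edit-distance similarity, threshold
# 0.6) to its own canonical term than to any other canonical of the same
# type, so similarity-based normalization recovers the canonical exactly.
# Variant spellings too far from their canonical for similarity matching
# (e.g. 清楚 -> 清晰) live in the explicit `replacements` table instead.

types:
  Location:
    左乳外上象限: [左侧乳腺外上象限]
    左乳外下象限: [左侧乳腺外下象限]
    左乳内上象限: [左侧乳腺内上象限]
    左乳内下象限: [左侧乳腺内下象限]
    右乳外上象限: [右侧乳腺外上象限]
    右乳外下象限: [右侧乳腺外下象限]
    右乳内上象限: [右侧乳腺内上象限]
    右乳内下象限: [右侧乳腺内下象限]
    左乳: [左乳腺]
    右乳: [右乳腺]
    双乳: [双乳腺]
    左腋下: [左侧腋下, 左腋窝]
    右腋下: [右侧腋下, 右腋窝]
  Mass:
    肿块: [肿块影]
    结节: [结节影, 结节灶]
  Calcification:
    钙化: [钙化灶, 钙化影]
  Structure:
    结构扭曲: [结构扭曲改变]
    结构紊乱: [结构排列紊乱]
  Lymph Node:
    淋巴结: [淋巴结影, 肿大淋巴结]
  Special:
    导管扩张: [导管扩张症]
    血管增粗: [血管影增粗]
    局灶性不对称: [局灶不对称]
  Merge:
    皮肤凹陷: [皮肤内陷]
    乳头内陷: [乳头凹陷]
    皮肤增厚: [皮肤局限增厚]
  Shape:
    卵圆形: [卵圆型]
    圆形: []
    不规则形: [不规则, 不规则型]
    分叶状: [浅分叶状]
    点状: [细点状]
    沙砾样: [砂砾样]
  Margin:
    毛刺状: [毛刺, 毛刺状边缘]
    清晰: [尚清晰]
    模糊: [较模糊]
  Size:
    约5mm: []
    约8mm: []
    约10mm: []
    约12mm: []
    约15mm: []
    约20mm: []
    约25mm: []
    约30mm: []
  Number:
    一: []
    两: []
    多发: []
    数个: []
  Density:
    高密度: [高密度影]
    等密度: [等密度影]
    低密度: [低密度影]
  Distribute:
    簇状分布: [呈簇状分布]
    散在分布: [散在性分布]
    区域性分布: [区域状分布]
  Category descriptions:
    多量腺体型: [多量腺体]
    致密型: [致密类型]
    少量腺体型: [少量腺体]
    脂肪型: [脂肪类型]
  Negation:
    未见: []
    未见明显: []
    无: []

# Explicit standard semantic replacements (misspellings or deprecated
# wordings mapped straight to their canonical term, checked before any
# similarity matching).
replacements:
  Shape:
    园形: 圆形
    卵园形: 卵圆形
  Margin:
    毛剌状: 毛刺状
    清楚: 清晰
    欠清: 模糊
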