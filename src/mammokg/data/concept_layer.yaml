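# Concept layer (schema layer) of the breast-cancer mammography knowledge graph.
#
# Three-level hierarchy: four first-level sign groups, nine second-level
# entities, and the attribute slots each entity owns (39 slots in total).
# All internal keys are English; `zh` gives the Chinese surface form used
# in reports.  The data layer instantiates 15 mammography feature types,
# each mapped to exactly one first-level parent.

first_level:
  - key: Common signs
    zh: 常见征象
  - key: Special signs
    zh: 特殊征象
  - key: Merge signs
    zh: 合并征象
  - key: Category descriptions
    zh: 分类描述

second_level:
  Mass: {parent: Common signs, zh: 肿块}
  Calcification: {parent: Common signs, zh: 钙化}
  Structure: {parent: Common signs, zh: 结构}
  Duct change: {parent: Special signs, zh: 导管改变}
  Intramammary lymph nodes: {parent: Special signs, zh: 乳内淋巴结}
  Asymmetrical: {parent: Special signs, zh: 不对称}
  Vascular change: {parent: Merge signs, zh: 血管改变}
  Axillary lymph nodes: {parent: Merge signs, zh: 腋窝淋巴结}
  Association anomaly: {parent: Merge signs, zh: 伴随异常}

# Attribute slots per owning entity (second-level entities plus the
# Category-descriptions first-level entity); 39 slots in total.
attributes:
  Mass: [Location, Margin, Number, Shape, Type, Size, Density, Negation]
  Calcification: [Location, Number, Shape, Type, Size, Density, Negation, Distribute]
  Structure: [Describe]
  Duct change: [Describe]
  Intramammary lymph nodes: [Location, Number, Shape, Negation, Describe]
  Asymmetrical: [Location, Describe]
  Vascular change: [Location, Shape, Negation]
  Axillary lymph nodes: [Location, Number, Shape, Negation, Describe]
  Association anomaly: [Location, Number, Negation, Describe]
  Category descriptions: [Location, Describe]

report_children: [Basic information, Mammography information, BI-RADS information]

predicates: [has_a, instance_of, part_of, select]

# Report-child entities licensed to select attribute values directly
# (demographics on Basic information; the assessment category on
# BI-RADS information).
select_subjects: [Basic information, BI-RADS information]

# The 15 data-layer feature types and their first-level parents.  Every
# report instantiates one part_of edge per feature type (15 per report).
feature_type_map:
  Mass: Common signs
  Calcification: Common signs
  Structure: Common signs
  Density: Common signs
  Distribute: Common signs
  Location: Common signs
  Margin: Common signs
  Number: Common signs
  Shape: Common signs
  Size: Common signs
  Negation: Common signs
  Special: Special signs
  Lymph Node: Special signs
  Merge: Merge signs
  Category descriptions: Category descriptions
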