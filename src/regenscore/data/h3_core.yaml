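# Default practice -> principle map for UK arable/mixed regenerative transitions.
# Nine core practices serving the five regenerative principles. Edit or replace
# this file to adapt the scoring system to another farming context.
window_years: 5
principles:
  - id: minimize-disturbance
    name: Minimize soil disturbance
  - id: soil-cover
    name: Keep soil covered
  - id: diversity
    name: Increase diversity
  - id: living-roots
    name: Maintain living roots
  - id: livestock
    name: Integrate livestock
practices:
  - id: no_till
    name: No or minimum tillage
    mode: area_proportional
    principles: [minimize-disturbance]
  - id: residue_retention
    name: Retention of crop residues
    mode: area_proportional
    principles: [soil-cover]
  - id: cover_crops
    name: Cover crops (incl. catch crops)
    mode: area_proportional
    principles: [soil-cover, diversity, living-roots]
  - id: spring_cropping
    name: Spring cropping
    mode: area_proportional
    principles: [diversity]
  - id: herbal_leys
    name: Herbal leys
    mode: binary_rotational
    principles: [minimize-disturbance, soil-cover, diversity, living-roots]
  - id: compaction_reduction
    name: Soil compaction reduction
    mode: area_proportional
    principles: [minimize-disturbance]
  - id: organic_matter
    name: Organic matter addition
    mode: binary_rotational
    principles: [livestock]
  - id: livestock_grazing
    name: Livestock grazing
    mode: area_proportional
    principles: [livestock]
  - id: crop_diversification
    name: Crop diversification
    mode: diversity_scaled
    principles: [diversity]
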