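gut	gut
oral	oral cavity dental plaque gingiva tonsil saliva
skin	skin
vagina	vaginal vagina
ocean	marine sea ocean seawater saline
freshwater	freshwater lake river
soil	soil agricultural field
hot_spring	hot spring
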