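subcategory	synonym
married	hubby
married	wedded
partnered	paramour
partnered	betrothed
relatives_unknown_involvement	stepbrother
relatives_unknown_involvement	godmother
caregiver_support	caretaker
caregiver_support	hired aide
living_with_others	cohabitating
living_with_others	shares apartment
community_connection	community ties
community_connection	neighbors assist
religious_connections	parish priest
religious_connections	devout
surrogate_identified	conference held
surrogate_identified	guardian appointed
unmarried	bachelor
unmarried	spinster
living_alone	solo dwelling
living_alone	unaccompanied
transitionally_situated	unhoused
transitionally_situated	transient lodging
surrogate_unidentified	kin untraceable
surrogate_unidentified	unlocatable kin
palliative_care	palliative approach
palliative_care	comfort focused care
hospice	respite house
hospice	terminal placement
advance_directives_available	dpoa
advance_directives_available	directive documented
advance_directives_unavailable	undocumented wishes
advance_directives_unavailable	unavailable paperwork
lacking_capacity	encephalopathic
lacking_capacity	delirious
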