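table	row	col	count
ct_by_bv	CT1	nugent_ge4	2
ct_by_bv	CT1	nugent_lt4	9
ct_by_bv	CT2	nugent_ge4	17
ct_by_bv	CT2	nugent_lt4	30
ct_by_bv	CT3	nugent_ge4	19
ct_by_bv	CT3	nugent_lt4	7
ct_by_bv	CT4	nugent_ge4	14
ct_by_bv	CT4	nugent_lt4	2
ct_by_sti	CT1	sti_pos	1
ct_by_sti	CT1	sti_neg	10
ct_by_sti	CT2	sti_pos	6
ct_by_sti	CT2	sti_neg	41
ct_by_sti	CT3	sti_pos	6
ct_by_sti	CT3	sti_neg	20
ct_by_sti	CT4	sti_pos	4
ct_by_sti	CT4	sti_neg	12
nugent_by_group	0-3	PrEP	31
nugent_by_group	0-3	nonPrEP	13
nugent_by_group	4-6	PrEP	21
nugent_by_group	4-6	nonPrEP	10
nugent_by_group	7-10	PrEP	9
nugent_by_group	7-10	nonPrEP	13
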