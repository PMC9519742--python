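group	interval	from_state	to_state	count
PrEP	baseline->month3	CT1	CT1	4
PrEP	baseline->month3	CT1	CT2	3
PrEP	baseline->month3	CT1	CT3	1
nonPrEP	baseline->month3	CT1	CT2	2
nonPrEP	baseline->month3	CT1	CT4	1
PrEP	baseline->month3	CT2	CT1	4
PrEP	baseline->month3	CT2	CT2	21
PrEP	baseline->month3	CT2	CT3	6
PrEP	baseline->month3	CT2	CT4	1
nonPrEP	baseline->month3	CT2	CT1	1
nonPrEP	baseline->month3	CT2	CT2	9
nonPrEP	baseline->month3	CT2	CT3	4
nonPrEP	baseline->month3	CT2	CT4	1
PrEP	month3->month6	CT2	CT1	3
PrEP	month3->month6	CT2	CT2	13
PrEP	month3->month6	CT2	CT3	5
nonPrEP	month3->month6	CT2	CT2	5
nonPrEP	month3->month6	CT2	CT3	2
nonPrEP	month3->month6	CT2	CT4	2
PrEP	baseline->month3	BV	Lacto	8
PrEP	baseline->month3	BV	BV	16
nonPrEP	baseline->month3	BV	Lacto	9
nonPrEP	baseline->month3	BV	BV	9
PrEP	month3->month6	BV	Lacto	6
PrEP	month3->month6	BV	BV	7
nonPrEP	month3->month6	BV	Lacto	3
nonPrEP	month3->month6	BV	BV	3
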