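# Six daily menu plans emulating conventional UK eating patterns.
# Plans 1-3: experimental period 1 (validation foods, Study 1).
# Plans 4-6: experimental period 2 (novel-biomarker foods, Study 2), including
# grapes in multiple forms, wholegrain/toasted products, legumes, curry and a
# low-calorie (artificially sweetened) beverage.  Gram amounts are deliberately
# not part of the fixture; portion sizes are configuration, not design.
plans:
  - plan_id: 1
    meals:
      breakfast:
        - {name: wholegrain cereal, food_group: wholegrain, preparation: with milk}
        - {name: orange juice, food_group: fruit, preparation: pasteurized}
      lunch:
        - {name: ham sandwich, food_group: processed_meat, preparation: white bread}
        - {name: apple, food_group: fruit, preparation: raw}
      snack:
        - {name: yogurt, food_group: dairy, preparation: plain}
      dinner:
        - {name: salmon fillet, food_group: fish, preparation: oven-baked}
        - {name: broccoli, food_group: vegetable, preparation: boiled}
        - {name: boiled potatoes, food_group: vegetable, preparation: boiled}
  - plan_id: 2
    meals:
      breakfast:
        - {name: porridge oats, food_group: wholegrain, preparation: boiled with milk}
        - {name: coffee, food_group: beverage, preparation: instant}
      lunch:
        - {name: tuna sandwich, food_group: fish, preparation: wholemeal bread}
        - {name: banana, food_group: fruit, preparation: raw}
      snack:
        - {name: digestive biscuit, food_group: baked, preparation: commercial}
      dinner:
        - {name: roast chicken, food_group: poultry, preparation: roasted}
        - {name: white rice, food_group: grain, preparation: boiled}
        - {name: carrots, food_group: vegetable, preparation: boiled}
  - plan_id: 3
    meals:
      breakfast:
        - {name: toasted wholemeal bread, food_group: toasted_grain, preparation: toasted}
        - {name: black tea, food_group: beverage, preparation: brewed}
      lunch:
        - {name: cheese sandwich, food_group: dairy, preparation: white bread}
        - {name: orange, food_group: fruit, preparation: raw}
      snack:
        - {name: mixed nuts, food_group: nuts, preparation: roasted}
      dinner:
        - {name: beef casserole, food_group: red_meat, preparation: stewed}
        - {name: garden peas, food_group: legumes, preparation: boiled}
        - {name: mashed potato, food_group: vegetable, preparation: boiled}
  - plan_id: 4
    meals:
      breakfast:
        - {name: strawberries, food_group: berries, preparation: fresh}
        - {name: wholegrain cereal, food_group: wholegrain, preparation: with milk}
        - {name: grape juice, food_group: grape, preparation: pasteurized}
      lunch:
        - {name: baked beans, food_group: legumes, preparation: canned, heated}
        - {name: toasted rye bread, food_group: toasted_grain, preparation: toasted}
      snack:
        - {name: low-calorie beverage, food_group: low_calorie_drink, preparation: carbonated}
      dinner:
        - {name: chicken curry, food_group: curry, preparation: clove-spiced, simmered}
        - {name: white rice, food_group: grain, preparation: boiled}
  - plan_id: 5
    meals:
      breakfast:
        - {name: porridge oats, food_group: wholegrain, preparation: microwaved with milk}
        - {name: raisins, food_group: grape, preparation: dried}
      lunch:
        - {name: tomato soup, food_group: tomato, preparation: canned, heated}
        - {name: wholemeal bread, food_group: wholegrain, preparation: untoasted}
      snack:
        - {name: peanuts, food_group: legumes, preparation: roasted}
      dinner:
        - {name: grilled white fish, food_group: fish, preparation: grilled}
        - {name: garden peas, food_group: legumes, preparation: boiled}
        - {name: red wine, food_group: grape, preparation: fermented}
  - plan_id: 6
    meals:
      breakfast:
        - {name: toasted sourdough rye bread, food_group: toasted_grain, preparation: toasted}
        - {name: sparkling grape juice, food_group: grape, preparation: carbonated}
      lunch:
        - {name: tofu stir fry, food_group: legumes, preparation: stir-fried soy}
        - {name: white rice, food_group: grain, preparation: boiled}
      snack:
        - {name: fruit smoothie, food_group: fruit, preparation: blended}
      dinner:
        - {name: steak pie, food_group: baked, preparation: high-temperature baked}
        - {name: green beans, food_group: vegetable, preparation: boiled}
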